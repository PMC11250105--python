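"""Marker-based islet cell-type composition from bulk matrices.

Scores each donor for alpha, beta, gamma/delta and acinar cell content from
the joint behaviour of cell-type marker features: per cell type, the first
principal component of the standardized marker submatrix (sign-oriented with
the mean marker profile), optionally shifted and row-normalized into
proportions summing to one.  The scores are relative across the cohort, not
absolute cell fractions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .association import bh_adjust
from .responders import dataclass_asdict, group_compare

__all__ = [
    "MarkerScoreComposition",
    "estimate_composition",
    "compare_composition",
    "read_marker_sets",
]


def read_marker_sets(path) -> dict[str, list]:
    """Two-column TSV (cell_type, feature_id) -> marker dict."""
    df = pd.read_csv(path, sep="\t")
    return {ct: sub["feature_id"].tolist()
            for ct, sub in df.groupby("cell_type", sort=True)}


class MarkerScoreComposition:
    """First-PC marker-score composition estimator (sklearn-style).

    Parameters
    ----------
    markers : mapping cell type -> marker feature ids (disjoint across types).
    mode : 'score' (raw oriented PC scores) or 'proportions' (scores shifted
        to non-negative and row-normalized to sum to 1).
    """

    def __init__(self, markers: dict[str, list], mode: str = "proportions"):
        self.markers = markers
        self.mode = mode

    def get_params(self, deep=True):
        return {"markers": self.markers, "mode": self.mode}

    def set_params(self, **p):
        for k, v in p.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None):
        """X is a features x donors matrix on a log-like scale."""
        if self.mode not in ("score", "proportions"):
            raise ValueError("mode must be 'score' or 'proportions'")
        seen: set = set()
        for ct, ids in self.markers.items():
            dup = seen & set(ids)
            if dup:
                raise ValueError(f"marker lists overlap across types: {dup}")
            seen |= set(ids)
        self.markers_used_ = {}
        for ct, ids in self.markers.items():
            present = [i for i in ids if i in X.index]
            if len(present) < 2:
                warnings.warn(f"cell type {ct!r} has <2 markers in the "
                              "matrix; dropped", stacklevel=2)
                continue
            self.markers_used_[ct] = present
        if not self.markers_used_:
            raise ValueError("no cell type has >= 2 markers in the matrix")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "markers_used_"):
            self.fit(X)
        donors = X.columns
        scores = {}
        for ct, ids in self.markers_used_.items():
            sub = X.loc[ids].to_numpy(dtype=float)
            sd = sub.std(axis=1, keepdims=True)
            ok = (sd > 0).ravel()
            if ok.sum() < 2:
                scores[ct] = np.zeros(len(donors))
                continue
            Z = (sub[ok] - sub[ok].mean(axis=1, keepdims=True)) / sd[ok]
            _, S, Vt = np.linalg.svd(Z, full_matrices=False)
            e = Vt[0]
            if np.corrcoef(e, Z.mean(axis=0))[0, 1] < 0:
                e = -e
            scores[ct] = e
        out = pd.DataFrame(scores, index=donors)
        if self.mode == "proportions":
            shifted = out - out.min(axis=0)
            rowsum = shifted.sum(axis=1)
            flat = rowsum == 0
            shifted.loc[flat] = 1.0 / shifted.shape[1]
            rowsum[flat] = 1.0
            out = shifted.div(rowsum, axis=0)
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def estimate_composition(matrix: pd.DataFrame, markers: dict[str, list],
                         mode: str = "proportions") -> pd.DataFrame:
    """Donor x cell-type composition estimate (see MarkerScoreComposition)."""
    return MarkerScoreComposition(markers, mode).fit_transform(matrix)


def compare_composition(estimate: pd.DataFrame, groups, ref: str = "ND",
                        test: str = "t") -> pd.DataFrame:
    """ND-vs-T2D contrast of each cell-type score, BH across cell types."""
    rows = []
    for ct in estimate.columns:
        gc = group_compare(estimate[ct].to_numpy(), groups, test=test,
                           ref=ref, feature=ct)
        rows.append(dataclass_asdict(gc))
    out = pd.DataFrame(rows).rename(columns={"feature": "cell_type"})
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
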