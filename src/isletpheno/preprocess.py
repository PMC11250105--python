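"""Proteome and transcriptome preprocessing.

Proteome chain: missingness filter (features undetected in more than half the
donors are dropped) -> per-donor median normalization and log10 transform ->
deterministic k-nearest-neighbour feature imputation.

Transcriptome chain: low-count filter (genes with fewer than 5 raw counts in
more than half the donors are dropped) -> log2(CPM + 0.5) transform ->
per-batch location/scale standardization to the pooled per-gene moments.  A
separate network-branch filter additionally trims the 15% lowest-mean and 15%
lowest-variance genes.

Matrices are features x donors DataFrames; missing entries are NaN.  The
sklearn-style transformers operate on that orientation directly and each
records its action in the matrix-level processing log helper.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MissingnessFilter",
    "MedianLog10Normalizer",
    "KNNFeatureImputer",
    "filter_missing",
    "normalize_proteome",
    "impute",
    "normalize_counts",
    "network_branch_filter",
    "batch_adjust",
    "feature_cv",
    "preprocess_proteome",
    "preprocess_rna",
]


class MissingnessFilter:
    """Drop features observed in too few donors.

    A feature is removed when its missing fraction strictly exceeds
    ``max_missing`` (a feature missing in exactly half the donors is kept).
    """

    def __init__(self, max_missing: float = 0.5):
        self.max_missing = max_missing

    def get_params(self, deep=True):
        return {"max_missing": self.max_missing}

    def set_params(self, **p):
        self.max_missing = p.get("max_missing", self.max_missing)
        return self

    def fit(self, X: pd.DataFrame, y=None):
        frac = X.isna().mean(axis=1)
        self.missing_fraction_ = frac
        self.support_ = (frac <= self.max_missing).to_numpy()
        if not self.support_.any():
            raise ValueError("all features exceed the missingness threshold")
        self.n_removed_ = int((~self.support_).sum())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[self.support_]

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


class MedianLog10Normalizer:
    """Divide each donor column by its median over observed entries, then log10.

    After the transform the observed-entry median of every column is 0.
    Stateless: fit is a no-op kept for pipeline compatibility.
    """

    def get_params(self, deep=True):
        return {}

    def set_params(self, **p):
        return self

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        vals = X.to_numpy(dtype=float)
        if np.nanmin(vals) <= 0:
            bad = np.argwhere(np.nan_to_num(vals, nan=1.0) <= 0)
            cells = [f"({X.index[i]}, {X.columns[j]})" for i, j in bad[:5]]
            raise ValueError(
                f"non-positive entries cannot be log-transformed: {cells}")
        med = np.nanmedian(vals, axis=0, keepdims=True)
        return pd.DataFrame(np.log10(vals / med), index=X.index,
                            columns=X.columns)

    def fit_transform(self, X, y=None):
        return self.transform(X)


class KNNFeatureImputer:
    """Impute missing entries from the k most correlated features.

    For each feature with missing donors, the k features with the highest
    absolute correlation (computed on mean-filled standardized data, used for
    neighbour selection only) that are observed for the donor in question are
    used as regressors in an OLS fit on the rows where the target is
    observed; the prediction fills the hole.  Falls back to the feature mean
    when the regression is unusable.  Deterministic given the matrix.
    """

    def __init__(self, k: int = 10):
        self.k = k

    def get_params(self, deep=True):
        return {"k": self.k}

    def set_params(self, **p):
        self.k = p.get("k", self.k)
        return self

    def fit(self, X: pd.DataFrame, y=None):
        if X.isna().all(axis=1).any():
            raise ValueError("feature with all entries missing")
        V = X.to_numpy(dtype=float)
        mean = np.nanmean(V, axis=1, keepdims=True)
        sd = np.nanstd(V, axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        Z = (V - mean) / sd
        Zf = np.nan_to_num(Z, nan=0.0)
        norm = np.sqrt((Zf ** 2).sum(axis=1, keepdims=True))
        norm[norm == 0] = 1.0
        self.neighbor_corr_ = (Zf / norm) @ (Zf / norm).T
        np.fill_diagonal(self.neighbor_corr_, 0.0)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "neighbor_corr_"):
            self.fit(X)
        V = X.to_numpy(dtype=float).copy()
        obs = ~np.isnan(V)
        feat_mean = np.nanmean(V, axis=1)
        for i in np.flatnonzero(~obs.all(axis=1)):
            miss = ~obs[i]
            order = np.argsort(-np.abs(self.neighbor_corr_[i]))
            # neighbours must be observed wherever the target is missing
            usable = order[obs[order][:, miss].all(axis=1)]
            nbrs = usable[: self.k]
            fit_rows = obs[i] & obs[nbrs].all(axis=0) if nbrs.size else None
            if not nbrs.size or fit_rows.sum() <= nbrs.size + 1:
                V[i, miss] = feat_mean[i]
                continue
            A = np.column_stack(
                [np.ones(int(fit_rows.sum()))] + [V[j, fit_rows] for j in nbrs])
            beta, *_ = np.linalg.lstsq(A, V[i, fit_rows], rcond=None)
            pred = beta[0] + V[nbrs][:, miss].T @ beta[1:]
            V[i, miss] = pred
        return pd.DataFrame(V, index=X.index, columns=X.columns)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


# --- module-level convenience wrappers -------------------------------------

def filter_missing(matrix: pd.DataFrame, max_missing: float = 0.5
                   ) -> pd.DataFrame:
    return MissingnessFilter(max_missing).fit_transform(matrix)


def normalize_proteome(matrix: pd.DataFrame) -> pd.DataFrame:
    return MedianLog10Normalizer().transform(matrix)


def impute(matrix: pd.DataFrame, method: str = "knn", k: int = 10
           ) -> pd.DataFrame:
    if method != "knn":
        raise ValueError("only the knn feature-regression imputer is available")
    return KNNFeatureImputer(k=k).fit_transform(matrix)


def normalize_counts(counts: pd.DataFrame, min_count: int = 5,
                     min_frac: float = 0.5) -> pd.DataFrame:
    """Low-count filter then log2(CPM + 0.5).

    Genes with fewer than ``min_count`` raw counts in more than ``min_frac``
    of donors are removed; the transform is a variance-stabilizing
    substitute, monotone in expression.
    """
    vals = counts.to_numpy()
    if np.any(vals < 0):
        raise ValueError("negative counts")
    low = (vals < min_count).mean(axis=1) > min_frac
    kept = counts.loc[~low]
    colsum = kept.to_numpy(dtype=float).sum(axis=0, keepdims=True)
    if np.any(colsum == 0):
        raise ValueError("donor with zero total counts after filtering")
    cpm = kept.to_numpy(dtype=float) / colsum * 1e6
    return pd.DataFrame(np.log2(cpm + 0.5), index=kept.index,
                        columns=kept.columns)


def network_branch_filter(matrix: pd.DataFrame, counts: pd.DataFrame,
                          trim: float = 0.15) -> pd.DataFrame:
    """Extra trims for the co-expression branch: drop the lowest-mean-count
    ``trim`` fraction of genes, then the lowest-variance fraction of the
    transformed values."""
    shared = matrix.index.intersection(counts.index)
    mean_counts = counts.loc[shared].mean(axis=1)
    keep = mean_counts.rank(pct=True, method="first") > trim
    sub = matrix.loc[shared[keep]]
    var = sub.var(axis=1)
    keep2 = var.rank(pct=True, method="first") > trim
    return sub.loc[keep2]


def batch_adjust(matrix: pd.DataFrame, batches) -> pd.DataFrame:
    """Per-gene location/scale standardization of each batch to pooled moments.

    Each batch's values are shifted and scaled so that, per gene, every batch
    has the pooled mean and pooled (sample) variance; singleton batches get a
    location-only adjustment with a warning.
    """
    batches = np.asarray(batches)
    if batches.size != matrix.shape[1]:
        raise ValueError("batch labels must match donor count")
    V = matrix.to_numpy(dtype=float).copy()
    pooled_mean = V.mean(axis=1, keepdims=True)
    pooled_sd = V.std(axis=1, ddof=1, keepdims=True)
    for b in pd.unique(batches):
        cols = batches == b
        sub = V[:, cols]
        m = sub.mean(axis=1, keepdims=True)
        if cols.sum() < 2:
            warnings.warn(f"singleton batch {b!r}: location-only adjustment",
                          stacklevel=2)
            V[:, cols] = sub - m + pooled_mean
            continue
        s = sub.std(axis=1, ddof=1, keepdims=True)
        scale = np.divide(pooled_sd, s, out=np.ones_like(s), where=s > 0)
        V[:, cols] = (sub - m) * scale + pooled_mean
    return pd.DataFrame(V, index=matrix.index, columns=matrix.columns)


def feature_cv(matrix: pd.DataFrame, log_base: float | None = None,
               ) -> pd.DataFrame:
    """Per-feature coefficient of variation on the natural scale.

    ``log_base`` back-transforms logged matrices before computing
    CV = SD/mean (population SD).  Zero-mean features are flagged.
    """
    V = matrix.to_numpy(dtype=float)
    if log_base is not None:
        V = np.power(float(log_base), V)
    mean = V.mean(axis=1)
    sd = V.std(axis=1, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean != 0, sd / mean, np.nan)
    return pd.DataFrame({"feature": matrix.index, "mean": mean, "sd": sd,
                         "cv": cv, "flag": np.where(mean == 0, "zero_mean", "")})


def compare_cv(protein_cv: pd.DataFrame, rna_cv: pd.DataFrame) -> dict:
    """Mann-Whitney comparison of protein vs transcript CV distributions."""
    a = protein_cv["cv"].dropna()
    b = rna_cv["cv"].dropna()
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"protein_median_cv": float(a.median()),
            "rna_median_cv": float(b.median()),
            "statistic": float(res.statistic), "p": float(res.pvalue)}


# --- full chains with processing logs --------------------------------------

def preprocess_proteome(matrix: pd.DataFrame, max_missing: float = 0.5,
                        k: int = 10) -> tuple[pd.DataFrame, list[dict]]:
    """Missingness filter -> median/log10 normalization -> KNN imputation."""
    log: list[dict] = []
    filt = MissingnessFilter(max_missing).fit(matrix)
    out = filt.transform(matrix)
    log.append({"step": "filter_missing", "max_missing": max_missing,
                "removed": filt.n_removed_, "kept": int(out.shape[0])})
    out = normalize_proteome(out)
    log.append({"step": "normalize_proteome", "transform": "median/log10"})
    out = impute(out, k=k)
    log.append({"step": "impute", "method": "knn_feature_regression", "k": k})
    return out, log


def preprocess_rna(counts: pd.DataFrame, batches=None, min_count: int = 5,
                   min_frac: float = 0.5) -> tuple[pd.DataFrame, list[dict]]:
    """Low-count filter -> log2(CPM + 0.5) -> batch adjustment."""
    log: list[dict] = []
    out = normalize_counts(counts, min_count, min_frac)
    log.append({"step": "normalize_counts", "min_count": min_count,
                "min_frac": min_frac, "removed": int(counts.shape[0] - out.shape[0]),
                "kept": int(out.shape[0]), "transform": "log2(CPM+0.5)"})
    if batches is not None:
        out = batch_adjust(out, batches)
        log.append({"step": "batch_adjust",
                    "n_batches": int(len(pd.unique(np.asarray(batches))))})
    return out, log
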