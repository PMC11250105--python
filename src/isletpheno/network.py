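"""Signed weighted co-expression networks and module-trait association.

The pipeline mirrors the weighted co-expression approach standard in the
field: a robust correlation (biweight midcorrelation) between features, a
signed soft-threshold adjacency a_ij = ((1 + cor_ij)/2)^beta, the topological
overlap measure (TOM) crediting shared neighbours, average-linkage
hierarchical clustering of 1 - TOM, a static tree cut into modules, module
eigengenes (first principal component, sign-oriented), and partial Pearson
correlation of eigengenes with donor traits given technical covariates.

The same code path serves proteome and transcriptome; only the soft
threshold differs (beta = 8 for proteomics, 20 for RNA).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .association import bh_adjust, partial_correlation

__all__ = [
    "bicor_matrix",
    "signed_adjacency",
    "topological_overlap",
    "CoexpressionNetwork",
    "detect_modules",
    "module_eigengenes",
    "module_trait_partial_correlation",
    "adjacency_edge_list",
]

logger = logging.getLogger(__name__)


def bicor_matrix(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Biweight midcorrelation between all feature pairs.

    Each feature is median-centred and weighted by w = (1 - u^2)^2 for
    |u| < 1 with u = (x - median) / (9 * MAD); features with MAD = 0 fall
    back to Pearson standardization (logged).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 4:
        raise ValueError("need a features x donors matrix with >= 4 donors")
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    degenerate = (mad == 0).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        u = (X - med) / (9.0 * mad)
    w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
    Y = (X - med) * w
    if degenerate.any():
        logger.info("bicor: %d features with MAD=0 fall back to Pearson",
                    int(degenerate.sum()))
        mean = X[degenerate].mean(axis=1, keepdims=True)
        Y[degenerate] = X[degenerate] - mean
    norm = np.sqrt((Y ** 2).sum(axis=1, keepdims=True))
    norm[norm == 0] = 1.0
    Y = Y / norm
    C = Y @ Y.T
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def signed_adjacency(cor: np.ndarray, beta: float) -> np.ndarray:
    """Signed soft-threshold adjacency a_ij = ((1 + cor_ij) / 2)^beta."""
    cor = np.asarray(cor, dtype=float)
    if np.any(cor < -1 - 1e-9) or np.any(cor > 1 + 1e-9):
        raise ValueError("correlations must lie in [-1, 1]")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    A = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(A, 1.0)
    return A


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with connectivity k_i = sum_{u != i} a_iu; TOM_ii = 1.
    """
    A = np.asarray(adjacency, dtype=float)
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    L = A0 @ A0           # sum over u != i, j since diag is zero
    k = A0.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + A0) / (kmin + 1.0 - A0)
    np.fill_diagonal(tom, 1.0)
    return tom


def _static_cut_labels(dissim: np.ndarray, min_module_size: int,
                       cut_height: float | None) -> np.ndarray:
    """Average-linkage clustering with a static height cut.

    With ``cut_height=None`` the cut is placed in the middle of the largest
    gap between consecutive merge heights, which separates tight planted
    modules (low merges) from the loose background (merges near the top of
    the dendrogram).  Clusters below ``min_module_size`` become unassigned
    (label 0).
    """
    n = dissim.shape[0]
    condensed = dissim[np.triu_indices(n, k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    heights = Z[:, 2]
    if cut_height is None:
        if np.ptp(heights) == 0:
            cut = heights[0] + 1.0  # degenerate: everything in one module
        else:
            gaps = np.diff(heights)
            g = int(np.argmax(gaps))
            cut = (heights[g] + heights[g + 1]) / 2.0
    else:
        cut = cut_height
    raw = hierarchy.fcluster(Z, t=cut, criterion="distance")
    labels = np.zeros(n, dtype=int)
    sizes = pd.Series(raw).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= min_module_size]
    # order modules by decreasing size
    for new, c in enumerate(sorted(kept, key=lambda c: -sizes[c]), start=1):
        labels[raw == c] = new
    return labels


class CoexpressionNetwork:
    """Signed weighted co-expression network with module detection.

    Parameters
    ----------
    beta : soft threshold (8 for proteome, 20 for RNA by convention here).
    corr : 'bicor' (robust, default) or 'pearson'.
    min_module_size : clusters smaller than this are left unassigned.
    cut_height : absolute static cut height on the 1-TOM dendrogram, or None
        for the automatic largest-gap cut.
    merge_threshold : modules whose eigengenes correlate above this are merged.

    Fitted attributes: ``correlation_``, ``adjacency_``, ``tom_``,
    ``labels_`` (0 = unassigned), ``eigengenes_`` (modules x donors),
    ``variance_explained_``, ``n_modules_``.
    """

    def __init__(self, beta: float = 8.0, corr: str = "bicor",
                 min_module_size: int = 30, cut_height: float | None = None,
                 merge_threshold: float = 0.75):
        self.beta = beta
        self.corr = corr
        self.min_module_size = min_module_size
        self.cut_height = cut_height
        self.merge_threshold = merge_threshold

    def get_params(self, deep=True):
        return {"beta": self.beta, "corr": self.corr,
                "min_module_size": self.min_module_size,
                "cut_height": self.cut_height,
                "merge_threshold": self.merge_threshold}

    def set_params(self, **p):
        for k, v in p.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None):
        """X is a features x donors matrix (complete, no NaN)."""
        if not (0.0 < self.merge_threshold < 1.0):
            raise ValueError("merge_threshold must be in (0, 1)")
        V = np.asarray(X, dtype=float)
        if np.isnan(V).any():
            raise ValueError("network input must be complete (impute first)")
        if self.corr == "bicor":
            C = bicor_matrix(V)
        elif self.corr == "pearson":
            C = np.corrcoef(V)
            np.fill_diagonal(C, 1.0)
        else:
            raise ValueError(f"unknown corr {self.corr!r}")
        A = signed_adjacency(C, self.beta)
        tom = topological_overlap(A)
        labels = _static_cut_labels(1.0 - tom, self.min_module_size,
                                    self.cut_height)
        labels = self._merge_similar(V, labels)
        self.correlation_, self.adjacency_, self.tom_ = C, A, tom
        self.labels_ = labels
        eig, ve = _eigengenes(V, labels)
        if isinstance(X, pd.DataFrame):
            eig = pd.DataFrame(eig, index=[f"M{m}" for m in
                                           range(1, eig.shape[0] + 1)],
                               columns=X.columns)
        self.eigengenes_ = eig
        self.variance_explained_ = ve
        self.n_modules_ = int(labels.max())
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def _merge_similar(self, V: np.ndarray, labels: np.ndarray) -> np.ndarray:
        """Iteratively merge module pairs whose eigengenes correlate above
        the merge threshold, then relabel by decreasing size."""
        labels = labels.copy()
        while labels.max() >= 2:
            eig, _ = _eigengenes(V, labels)
            C = np.corrcoef(eig)
            np.fill_diagonal(C, -np.inf)
            i, j = np.unravel_index(np.argmax(C), C.shape)
            if C[i, j] <= self.merge_threshold:
                break
            labels[labels == j + 1] = i + 1
            labels = _relabel_by_size(labels)
        return _relabel_by_size(labels)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    out = np.zeros_like(labels)
    sizes = pd.Series(labels[labels > 0]).value_counts()
    for new, old in enumerate(sizes.index, start=1):
        out[labels == old] = new
    return out


def _eigengenes(V: np.ndarray, labels: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    n_mod = int(labels.max())
    n_donors = V.shape[1]
    eig = np.zeros((n_mod, n_donors))
    ve = np.zeros(n_mod)
    for m in range(1, n_mod + 1):
        sub = V[labels == m]
        sd = sub.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        Z = (sub - sub.mean(axis=1, keepdims=True)) / sd
        if Z.shape[0] == 1:
            e = Z[0] / np.linalg.norm(Z[0])
            ve[m - 1] = 1.0
        else:
            U, S, Vt = np.linalg.svd(Z, full_matrices=False)
            e = Vt[0]
            ve[m - 1] = S[0] ** 2 / (S ** 2).sum()
        # orient so the eigengene tracks higher module abundance
        if np.corrcoef(e, Z.mean(axis=0))[0, 1] < 0:
            e = -e
        eig[m - 1] = e
    return eig, ve


def detect_modules(matrix: pd.DataFrame, beta: float = 8.0,
                   corr: str = "bicor", min_module_size: int = 30,
                   cut_height: float | None = None,
                   merge_threshold: float = 0.75) -> pd.DataFrame:
    """Feature -> module assignment table (module 0 = unassigned)."""
    net = CoexpressionNetwork(beta, corr, min_module_size, cut_height,
                              merge_threshold).fit(matrix)
    idx = matrix.index if isinstance(matrix, pd.DataFrame) else np.arange(
        np.asarray(matrix).shape[0])
    return pd.DataFrame({"feature": idx, "module": net.labels_})


def module_eigengenes(matrix: pd.DataFrame, assignment: pd.DataFrame
                      ) -> tuple[pd.DataFrame, np.ndarray]:
    """Eigengenes (modules x donors, unit norm) for an existing assignment."""
    labels = assignment.set_index("feature")["module"].reindex(
        matrix.index).to_numpy()
    if int(labels.max()) < 1:
        raise ValueError("no modules in assignment")
    eig, ve = _eigengenes(np.asarray(matrix, dtype=float), labels)
    eigdf = pd.DataFrame(eig, index=[f"M{m}" for m in range(1, eig.shape[0] + 1)],
                         columns=matrix.columns)
    return eigdf, ve


def module_trait_partial_correlation(eigengenes: pd.DataFrame,
                                     traits: pd.DataFrame,
                                     covariates: pd.DataFrame | None = None,
                                     ) -> pd.DataFrame:
    """Partial Pearson correlation of each eigengene with each trait.

    Residualizes both sides on the technical covariate set (e.g. purity,
    culture time, digestion time, cold ischemia time); BH across all
    module x trait cells, significance flagged at q < 0.05.
    """
    Z = None
    if covariates is not None and covariates.shape[1]:
        Zdf = covariates.astype(float)
        keep, dropped = [], []
        for c in Zdf.columns:
            cand = Zdf[keep + [c]].to_numpy()
            if np.linalg.matrix_rank(np.column_stack([np.ones(len(cand)), cand])
                                     ) == len(keep) + 2:
                keep.append(c)
            else:
                dropped.append(c)
        if dropped:
            logger.warning("dropping collinear covariates: %s", dropped)
        Z = Zdf[keep].to_numpy() if keep else None
    rows = []
    for mod in eigengenes.index:
        e = eigengenes.loc[mod].to_numpy(dtype=float)
        for trait in traits.columns:
            tv = traits[trait].to_numpy(dtype=float)
            ok = ~np.isnan(tv)
            try:
                r, p = partial_correlation(
                    e[ok], tv[ok], Z[ok] if Z is not None else None)
            except ValueError:
                r, p = np.nan, np.nan
            rows.append({"module": mod, "trait": trait, "r": r, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < 0.05
    return out


def adjacency_edge_list(adjacency: np.ndarray, features,
                        labels: np.ndarray | None = None,
                        min_weight: float = 0.2) -> pd.DataFrame:
    """Thresholded edge list for export to graph viewers.

    Keeps edges with adjacency >= ``min_weight`` between assigned features
    (when labels are given) and drops isolated nodes implicitly.
    """
    A = np.asarray(adjacency)
    features = np.asarray(features)
    iu, ju = np.triu_indices(A.shape[0], k=1)
    w = A[iu, ju]
    keep = w >= min_weight
    if labels is not None:
        keep &= (labels[iu] > 0) & (labels[ju] > 0)
    return pd.DataFrame({"source": features[iu[keep]],
                         "target": features[ju[keep]],
                         "weight": w[keep]})
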