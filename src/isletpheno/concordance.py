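"""RNA-protein concordance analyses.

Across-gene correlation (do abundant transcripts make abundant proteins?),
within-gene correlation (does a gene's transcript level track its protein
level across donors?), rank-rank hypergeometric overlap (RRHO) of two
differential signatures, and hypergeometric over-representation analysis
(ORA) against user gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust

__all__ = [
    "across_gene_correlation",
    "within_gene_correlation",
    "rrho_map",
    "RRHOGrid",
    "ora_hypergeometric",
    "read_gmt",
]


def _align(protein: pd.DataFrame, rna: pd.DataFrame,
           mapping: pd.Series | None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Row-align a protein and an RNA matrix on shared genes.

    ``mapping`` maps protein feature ids to gene ids (defaults to identity
    of the index)."""
    if mapping is not None:
        prot = protein.copy()
        prot.index = mapping.reindex(protein.index).to_numpy()
        prot = prot[~pd.isna(prot.index)]
    else:
        prot = protein
    shared = prot.index.intersection(rna.index)
    return prot.loc[shared], rna.loc[shared]


def across_gene_correlation(protein: pd.DataFrame, rna: pd.DataFrame,
                            mapping: pd.Series | None = None,
                            ) -> tuple[float, int]:
    """Pearson r between per-gene mean log protein and mean log RNA.

    Both matrices must already be on a log scale; the correlation is over
    genes shared between the two matrices.  Returns (r, n_shared_genes).
    """
    prot, rna_m = _align(protein, rna, mapping)
    if len(prot) < 3:
        raise ValueError("need >= 3 shared genes")
    pm = prot.mean(axis=1).to_numpy()
    rm = rna_m.mean(axis=1).to_numpy()
    r = float(np.corrcoef(pm, rm)[0, 1])
    return r, len(prot)


def within_gene_correlation(protein: pd.DataFrame, rna: pd.DataFrame,
                            mapping: pd.Series | None = None,
                            ) -> tuple[pd.DataFrame, dict]:
    """Per-gene Pearson correlation across shared donors, BH-adjusted.

    Returns the per-gene table and summary fractions of genes with
    significant positive / significant negative / non-significant
    correlation at q < 0.05 (the three fractions partition the genes).
    """
    prot, rna_m = _align(protein, rna, mapping)
    donors = prot.columns.intersection(rna_m.columns)
    if len(donors) < 4:
        raise ValueError("need >= 4 shared donors")
    P = prot[donors].to_numpy(dtype=float)
    R = rna_m[donors].to_numpy(dtype=float)
    n = len(donors)

    def _std(M):
        Z = M - M.mean(axis=1, keepdims=True)
        s = np.sqrt((Z ** 2).sum(axis=1, keepdims=True))
        bad = (s == 0).ravel()
        s[s == 0] = 1.0
        return Z / s, bad

    Zp, badp = _std(P)
    Zr, badr = _std(R)
    r = (Zp * Zr).sum(axis=1)
    bad = badp | badr
    r_ = np.clip(r, -0.9999999999, 0.9999999999)
    t = r_ * np.sqrt((n - 2) / (1.0 - r_ ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(bad, np.nan, p)
    table = pd.DataFrame({"gene": prot.index, "r": np.where(bad, np.nan, r),
                          "p": p, "q": bh_adjust(p), "n": n})
    sig = table["q"] < 0.05
    total = int((~table["q"].isna()).sum())
    summary = {
        "frac_positive_significant": float((sig & (table["r"] > 0)).sum()) / total,
        "frac_negative_significant": float((sig & (table["r"] < 0)).sum()) / total,
        "frac_nonsignificant": float((~sig & ~table["q"].isna()).sum()) / total,
        "n_genes": total,
    }
    return table, summary


@dataclass
class RRHOGrid:
    """Rank-rank hypergeometric overlap grid.

    ``logp`` holds signed -log10 hypergeometric p-values: positive cells mark
    over-enrichment of the overlap between the two top lists, negative cells
    under-enrichment.  Row i / column j correspond to top-(i+1)*step genes of
    x and y respectively.
    """

    step: int
    thresholds: np.ndarray
    logp: np.ndarray
    counts: np.ndarray
    metric: str = "signed_logp"

    @property
    def max_logp(self) -> float:
        return float(np.nanmax(self.logp))


def _rank_order(scores: pd.Series) -> np.ndarray:
    """Gene order from most-up to most-down: descending signed score with
    ties broken by gene id for determinism."""
    order = scores.to_frame("score").assign(gene=scores.index.astype(str))
    order = order.sort_values(["score", "gene"], ascending=[False, True])
    return order.index.to_numpy()


def rrho_map(score_x: pd.Series, score_y: pd.Series,
             step: int | None = None) -> RRHOGrid:
    """Rank-rank hypergeometric overlap between two gene-level signatures.

    Scores (e.g. direction-signed -log10 p or log2 fold change) are ranked
    from most-up-regulated to most-down-regulated over the shared gene
    universe; for each pair of list-depth thresholds the overlap of the two
    top lists is scored with an upper-tail (over-enrichment, positive cells)
    or lower-tail (under-enrichment, negative cells) hypergeometric test.

    ``step`` defaults to 100 for large universes and ceil(m/50) when
    m < 5000.
    """
    shared = score_x.index.intersection(score_y.index)
    m = len(shared)
    if m < 2:
        raise ValueError("need at least 2 shared genes")
    if step is None:
        step = 100 if m >= 5000 else int(np.ceil(m / 50))
    if step >= m:
        raise ValueError(f"step {step} must be smaller than universe {m}")
    ox = _rank_order(score_x.loc[shared])
    oy = _rank_order(score_y.loc[shared])
    # position of each gene in y's ranking
    pos_y = pd.Series(np.arange(m), index=oy)
    x_pos_in_y = pos_y.loc[ox].to_numpy()

    ks = np.arange(step, m + 1, step)
    if ks[-1] != m:
        ks = np.append(ks, m)
    # overlap counts by cumulative counting: indicator[i, j] = 1 if gene at
    # x-rank i sits within top j of y
    grid_counts = np.zeros((ks.size, ks.size), dtype=int)
    for bi, i in enumerate(ks):
        in_top = x_pos_in_y[:i]
        # y-positions are 0-based: top-j of y means position < j
        grid_counts[bi] = np.searchsorted(np.sort(in_top), ks, side="left")
    logp = np.zeros_like(grid_counts, dtype=float)
    for bi, i in enumerate(ks):
        for bj, j in enumerate(ks):
            k = grid_counts[bi, bj]
            expected = i * j / m
            if k >= expected:
                p = stats.hypergeom.sf(k - 1, m, i, j)
                logp[bi, bj] = -np.log10(max(p, 1e-320))
            else:
                p = stats.hypergeom.cdf(k, m, i, j)
                logp[bi, bj] = np.log10(max(p, 1e-320))
    return RRHOGrid(step=step, thresholds=ks, logp=logp, counts=grid_counts)


def ora_hypergeometric(hits, gene_sets: dict[str, list], universe,
                       ) -> pd.DataFrame:
    """Over-representation of a hit list in each gene set.

    Upper-tail hypergeometric with the shared detection universe as
    background; sets are intersected with the universe and deduplicated;
    BH across sets.
    """
    universe = pd.unique(pd.Series(list(universe)))
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    hits = set(hits)
    if not hits:
        raise ValueError("empty hit list")
    if not hits <= uni:
        raise ValueError("hits must be a subset of the universe")
    M, N = len(uni), len(hits)
    rows = []
    for name, members in gene_sets.items():
        mem = set(members) & uni
        K = len(mem)
        k = len(mem & hits)
        p = float(stats.hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        rows.append({"set": name, "set_size": K, "hits": N, "overlap": k,
                     "universe": M, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def read_gmt(path) -> dict[str, list]:
    """Read a GMT gene-set file (set name, description, member ids)."""
    sets: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
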