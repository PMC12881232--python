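"""Dynamic-network-biomarker statistics and disease-gene nomination.

A candidate gene set (typically the k lowest-curvature genes of a critical
unit) is corroborated with the classic DNB composite index

    I_DNB = SD_in * PCC_in / PCC_out,

where SD_in is the mean per-gene standard deviation inside the set, PCC_in
the mean absolute Pearson correlation over distinct in-set pairs, and
PCC_out the mean absolute correlation between in-set and out-of-set genes.
At a tipping point the in-set variance and correlation rise while the
coupling to the rest of the network falls, so I_DNB peaks.  The module also
provides the edge count of the in-set correlation network, Student-t
differential expression, and extraction of out-of-set genes strongly
correlated to the set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._correlation import pearson_matrix, pearson_pvalues
from .data import ExpressionMatrix

__all__ = [
    "DnbIndex",
    "pcc_in",
    "pcc_out",
    "dnb_index",
    "network_edges",
    "differential_genes",
    "correlated_partners",
    "overlap",
]


def _set_indices(X: ExpressionMatrix, gene_set: Sequence[str]) -> np.ndarray:
    lookup = {f: i for i, f in enumerate(X.feature_ids)}
    missing = [g for g in gene_set if g not in lookup]
    if missing:
        raise KeyError(f"gene set members absent from matrix: {missing[:10]}")
    return np.array([lookup[g] for g in gene_set], dtype=int)


def pcc_in(X: ExpressionMatrix, gene_set: Sequence[str],
           denominator: str = "pairs") -> float:
    """Mean |PCC| inside the gene set.

    ``denominator='pairs'`` (default) averages over the C(n,2) distinct
    unordered pairs, matching the verbal "average correlation among the
    genes"; ``denominator='n'`` instead divides the pair sum by the set size,
    an alternative normalisation sometimes used for a size-n DNB set.
    """
    idx = _set_indices(X, gene_set)
    if idx.size < 2:
        raise ValueError("gene set needs at least 2 genes")
    r = np.abs(pearson_matrix(X.values[:, idx]))
    iu = np.triu_indices(idx.size, k=1)
    total = float(r[iu].sum())
    if denominator == "pairs":
        return total / len(iu[0])
    if denominator == "n":
        return total / idx.size
    raise ValueError(f"unknown denominator {denominator!r}")


def pcc_out(X: ExpressionMatrix, gene_set: Sequence[str]) -> float:
    """Mean |PCC| over all (in-set, out-of-set) gene pairs."""
    idx = _set_indices(X, gene_set)
    out = np.setdiff1d(np.arange(X.n_features), idx)
    if out.size == 0:
        raise ValueError("gene set covers every feature; no out-set genes")
    r = pearson_matrix(X.values)
    return float(np.abs(r[np.ix_(idx, out)]).mean())


@dataclass
class DnbIndex:
    gene_set: list[str]
    sd_in: float
    pcc_in: float
    pcc_out: float
    i_dnb: float


def dnb_index(X: ExpressionMatrix, gene_set: Sequence[str],
              epsilon: float | None = None,
              denominator: str = "pairs") -> DnbIndex:
    """Composite DNB index of a gene set: SD_in * PCC_in / PCC_out.

    ``sd_in`` is the mean of per-gene sample standard deviations (ddof=1).
    A zero PCC_out is an error unless ``epsilon`` substitutes a floor.
    """
    idx = _set_indices(X, gene_set)
    sd_in = float(X.values[:, idx].std(axis=0, ddof=1).mean())
    p_in = pcc_in(X, gene_set, denominator=denominator)
    p_out = pcc_out(X, gene_set)
    if p_out == 0.0:
        if epsilon is None:
            raise ZeroDivisionError(
                "PCC_out is zero; pass epsilon (e.g. 1e-6) to floor it"
            )
        p_out = epsilon
    return DnbIndex(list(gene_set), sd_in, p_in, p_out, sd_in * p_in / p_out)


def network_edges(X: ExpressionMatrix, gene_set: Sequence[str],
                  pcc_threshold: float = 0.7, p_threshold: float = 0.01) -> int:
    """Number of unordered in-set pairs with |PCC| > pcc_threshold and
    correlation-test p < p_threshold."""
    idx = _set_indices(X, gene_set)
    if X.n_samples < 3:
        raise ValueError("edge counting needs at least 3 samples")
    sub = X.values[:, idx]
    r = pearson_matrix(sub)
    p = pearson_pvalues(r, X.n_samples)
    iu = np.triu_indices(idx.size, k=1)
    return int(((np.abs(r[iu]) > pcc_threshold) & (p[iu] < p_threshold)).sum())


def differential_genes(
    Xa: ExpressionMatrix,
    Xb: ExpressionMatrix,
    alpha: float = 0.05,
    equal_var: bool = True,
    correction: str | None = None,
) -> list[str]:
    """Per-gene two-sided Student t-test between two groups; returns genes
    with p < alpha.  No multiplicity correction by default (``correction=
    'bh'`` applies Benjamini-Hochberg); ``equal_var=False`` switches to the
    Welch test for degenerate within-group variances."""
    if Xa.feature_ids != Xb.feature_ids:
        raise ValueError("groups have mismatched features")
    if Xa.n_samples < 2 or Xb.n_samples < 2:
        raise ValueError("each group needs at least 2 samples")
    _, p = stats.ttest_ind(Xa.values, Xb.values, axis=0, equal_var=equal_var)
    p = np.nan_to_num(p, nan=1.0)
    if correction == "bh":
        p = stats.false_discovery_control(p, method="bh")
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return [f for f, pi in zip(Xa.feature_ids, p) if pi < alpha]


def correlated_partners(
    X: ExpressionMatrix,
    gene_set: Sequence[str],
    pcc_threshold: float = 0.7,
    p_threshold: float = 0.01,
) -> list[str]:
    """Out-of-set genes with at least one qualifying correlation
    (|PCC| > pcc_threshold, p < p_threshold) to any in-set gene."""
    idx = _set_indices(X, gene_set)
    out = np.setdiff1d(np.arange(X.n_features), idx)
    if out.size == 0:
        raise ValueError("gene set covers every feature; no out-set genes")
    if X.n_samples < 3:
        raise ValueError("correlation test needs at least 3 samples")
    r = pearson_matrix(X.values)
    p = pearson_pvalues(r, X.n_samples)
    block_r = np.abs(r[np.ix_(idx, out)])
    block_p = p[np.ix_(idx, out)]
    hit = ((block_r > pcc_threshold) & (block_p < p_threshold)).any(axis=0)
    return [X.feature_ids[j] for j in out[hit]]


def overlap(list_a: Sequence[str], list_b: Sequence[str]) -> list[str]:
    """Set intersection preserving the order of ``list_a`` (for Venn-style
    overlap counts between gene lists)."""
    b = set(list_b)
    return [g for g in list_a if g in b]
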