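"""Differential coexpression: link filtering, per-gene statistic, permutation p-values, BH-FDR.

The two-condition analysis works on Pearson correlation matrices computed
separately within each condition. A *link* (unordered gene pair) is retained
by half-thresholding: the pair survives when the larger of its two
condition-wise absolute correlations reaches the ``(1 - q)``-quantile of the
pooled ``|r|`` distribution. A gene's differential-coexpression statistic is
the root-mean-square correlation change over its retained links,

    dC_g = sqrt( sum_links (r1 - r2)^2 / n_links ),

which lies in [0, 2] and is symmetric in the two conditions. Significance is
assessed by permuting condition labels across samples and recomputing the
*entire* statistic — correlations, link filter and dC — inside each
permutation, which keeps observed and permuted values exchangeable, so the
per-gene add-one p-values are uniform under the null. Genes with
Benjamini–Hochberg FDR strictly below the cutoff (default 0.25) are called
differentially coexpressed genes (DCGs), and the DC-links reported are the
retained links with both endpoints DCGs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionDataset

__all__ = [
    "correlation_matrix",
    "condition_correlations",
    "filter_links",
    "gene_dc_statistic",
    "permutation_pvalues",
    "bh_adjust",
    "select_dcgs",
    "dcg_analysis",
    "DCGResult",
]


def correlation_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson correlation matrix of ``X`` (genes × samples).

    Returns ``(R, zero_variance)``: a symmetric matrix with unit diagonal and
    entries clipped to [−1, 1], plus a boolean mask of zero-variance rows.
    Zero-variance rows get correlation 0 off-diagonal so downstream sums stay
    finite.
    """
    X = np.asarray(X, dtype=float)
    Z = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Z**2).sum(axis=1))
    zero = norm == 0
    safe = np.where(zero, 1.0, norm)
    Z = Z / safe[:, None]
    Z[zero] = 0.0
    R = Z @ Z.T
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    return R, zero


def condition_correlations(dataset: ExpressionDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-condition gene × gene Pearson correlation matrices ``(R1, R2)``."""
    X = dataset.values
    out = []
    for c in (1, 2):
        R, zero = correlation_matrix(X[:, dataset.condition_columns(c)])
        if zero.any():
            names = [dataset.gene_ids[i] for i in np.flatnonzero(zero)[:5]]
            warnings.warn(
                f"{int(zero.sum())} zero-variance gene(s) in condition {c} "
                f"(e.g. {names}); their correlations are set to 0",
                stacklevel=2,
            )
        out.append(R)
    return out[0], out[1]


def filter_links(corr1: np.ndarray, corr2: np.ndarray, q: float) -> np.ndarray:
    """Half-thresholding link filter.

    A link (a, b) is retained iff ``max(|r1_ab|, |r2_ab|) >= t`` where ``t``
    is the ``(1 - q)``-quantile of the pooled ``|r|`` values of all links in
    both conditions. ``q = 1`` retains every link. Returns a symmetric boolean
    matrix with a False diagonal.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("q must be in (0, 1]")
    n = corr1.shape[0]
    iu = np.triu_indices(n, k=1)
    a1 = np.abs(corr1[iu])
    a2 = np.abs(corr2[iu])
    pooled = np.concatenate([a1, a2])
    threshold = np.quantile(pooled, 1.0 - q)
    keep = np.maximum(a1, a2) >= threshold
    mask = np.zeros((n, n), dtype=bool)
    mask[iu] = keep
    mask |= mask.T
    return mask


def gene_dc_statistic(r1: np.ndarray, r2: np.ndarray) -> float:
    """Root-mean-square correlation change over one gene's retained links.

    ``r1`` and ``r2`` are the gene's link correlations in conditions 1 and 2;
    a gene with no retained links scores 0.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if r1.shape != r2.shape:
        raise ValueError("r1 and r2 must have equal length")
    if r1.size == 0:
        return 0.0
    return float(np.sqrt(np.mean((r1 - r2) ** 2)))


def _gene_dc_vector(corr1: np.ndarray, corr2: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Vectorized dC over all genes given the retained-link mask."""
    D = (corr1 - corr2) ** 2
    s = np.where(mask, D, 0.0).sum(axis=1)
    c = mask.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dC = np.sqrt(s / np.maximum(c, 1))
    dC[c == 0] = 0.0
    return dC


def _dc_for_split(X: np.ndarray, cols1: np.ndarray, cols2: np.ndarray, q: float) -> np.ndarray:
    R1, _ = correlation_matrix(X[:, cols1])
    R2, _ = correlation_matrix(X[:, cols2])
    mask = filter_links(R1, R2, q)
    return _gene_dc_vector(R1, R2, mask)


def permutation_pvalues(
    dataset: ExpressionDataset,
    n_perm: int = 1000,
    q: float = 0.25,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene permutation p-values for the dC statistic.

    Condition labels are permuted across all samples ``n_perm`` times and the
    full statistic (correlations, link filter, dC) is recomputed each time.
    The add-one estimator ``p = (1 + #{dC* >= dC}) / (1 + n_perm)`` avoids
    zero p-values, so the smallest attainable p is ``1 / (1 + n_perm)``.

    Returns ``(p, dC_observed)``; identical seed gives identical p.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    X = dataset.values
    idx1 = dataset.condition_columns(1)
    idx2 = dataset.condition_columns(2)
    dc_obs = _dc_for_split(X, idx1, idx2, q)
    # permute over the sorted column set so equal-sized condition swaps are
    # exactly invariant
    all_cols = np.sort(np.concatenate([idx1, idx2]))
    n1 = len(idx1)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(dc_obs.shape[0], dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(all_cols)
        dc_perm = _dc_for_split(X, perm[:n1], perm[n1:], q)
        exceed += dc_perm >= dc_obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    return p, dc_obs


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    ``fdr_i = min_{k : p_(k) >= p_(i)} p_(k) * m / k`` clipped at 1;
    order-preserving under permutation of the input.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    fdr_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    fdr = np.empty(m, dtype=float)
    fdr[order] = np.minimum(fdr_sorted, 1.0)
    return fdr


def select_dcgs(
    table: pd.DataFrame,
    links: pd.DataFrame,
    fdr_cutoff: float = 0.25,
) -> tuple[set[str], pd.DataFrame]:
    """Call DCGs at ``fdr < cutoff`` (strict) and keep links between two DCGs.

    ``table`` must have columns ``gene`` and ``fdr``; ``links`` must have
    ``gene_a`` and ``gene_b``. Returns the DCG set and the DC-link rows.
    """
    dcgs = set(table.loc[table["fdr"] < fdr_cutoff, "gene"])
    dc = links[links["gene_a"].isin(dcgs) & links["gene_b"].isin(dcgs)]
    return dcgs, dc.reset_index(drop=True)


@dataclass
class DCGResult:
    """Everything the DCG stage produced, for downstream stages and export."""

    table: pd.DataFrame  # gene, dC, p, fdr, is_dcg
    links: pd.DataFrame  # retained links: gene_a, gene_b, r1, r2, d
    dc_links: pd.DataFrame  # retained links with both endpoints DCGs
    dcgs: set[str]
    corr1: np.ndarray
    corr2: np.ndarray
    link_mask: np.ndarray


def dcg_analysis(
    dataset: ExpressionDataset,
    q: float = 0.25,
    n_perm: int = 1000,
    fdr_cutoff: float = 0.25,
    seed: int = 0,
) -> DCGResult:
    """Run the full DCG stage on a dataset.

    Computes condition correlations, retains links with the ``q``-quantile
    half-thresholding filter, scores each gene with the RMS correlation
    change, attaches permutation p-values and BH-FDR, and calls DCGs at
    ``fdr < fdr_cutoff`` (strict).
    """
    if 1.0 / (1.0 + n_perm) >= fdr_cutoff:
        warnings.warn(
            f"n_perm={n_perm} cannot resolve p-values below the FDR cutoff "
            f"{fdr_cutoff}; increase n_perm",
            stacklevel=2,
        )
    corr1, corr2 = condition_correlations(dataset)
    mask = filter_links(corr1, corr2, q)
    p, dc_obs = permutation_pvalues(dataset, n_perm=n_perm, q=q, seed=seed)
    fdr = bh_adjust(p)
    table = pd.DataFrame(
        {
            "gene": dataset.gene_ids,
            "dC": dc_obs,
            "p": p,
            "fdr": fdr,
            "is_dcg": fdr < fdr_cutoff,
        }
    )
    ia, ib = np.where(np.triu(mask, k=1))
    genes = np.array(dataset.gene_ids, dtype=object)
    ga, gb = genes[ia], genes[ib]
    swap = ga > gb  # canonical order: gene_a < gene_b lexicographically
    ga[swap], gb[swap] = gb[swap], ga[swap]
    links = pd.DataFrame(
        {
            "gene_a": ga,
            "gene_b": gb,
            "r1": corr1[ia, ib],
            "r2": corr2[ia, ib],
        }
    )
    links["d"] = np.abs(links["r1"] - links["r2"])
    links = links.sort_values(["gene_a", "gene_b"], kind="mergesort").reset_index(drop=True)
    dcgs, dc_links = select_dcgs(table, links, fdr_cutoff=fdr_cutoff)
    return DCGResult(
        table=table,
        links=links,
        dc_links=dc_links,
        dcgs=dcgs,
        corr1=corr1,
        corr2=corr2,
        link_mask=mask,
    )
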