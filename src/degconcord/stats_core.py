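"""Self-contained statistical primitives used throughout the pipeline.

Benjamini-Hochberg FDR adjustment, the two-sided Fisher exact test on 2x2
tables, quantile normalization and Tukey median polish.  The latter two
together form the simplified RMA-style summarization (quantile-normalize
probe columns, then polish each gene's probe-by-sample block) used to study
how microarray preprocessing narrows and shifts fold-change distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "MedianPolishResult",
    "bh_adjust",
    "fisher_exact_2x2",
    "quantile_normalize",
    "median_polish",
    "rma_summarize",
]


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adjusted_i = min over j with p_(j) >= p_(i) of min(1, p_(j) * m / rank_j),
    where m counts the non-missing entries.  Missing (NaN) entries are passed
    through as NaN and excluded from m.  Any p outside [0, 1] is an error.
    """
    p = np.asarray(pvals, dtype=float)
    flat = p.ravel()
    mask = ~np.isnan(flat)
    vals = flat[mask]
    if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(flat.shape, np.nan)
    m = vals.size
    if m:
        order = np.argsort(vals, kind="mergesort")
        ranked = vals[order] * m / np.arange(1, m + 1)
        # step-up: running minimum from the largest p downwards
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        np.clip(adj, None, 1.0, out=adj)
        tmp = np.empty(m)
        tmp[order] = adj
        out[mask] = tmp
    return out.reshape(p.shape)


# ---------------------------------------------------------------------------
# Fisher exact test


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table; rows = in-group/out-group, columns = two conditions."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cells must be non-negative integers, got {cells}")
        if sum(cells) == 0:
            raise ValueError("at least one cell must be positive")


#: relative tolerance when comparing point probabilities to the observed one,
#: so tables tied with the observed probability are not excluded by rounding
POINT_PROB_RTOL = 1e-7


def _hypergeom_pmf(k: np.ndarray, n: int, n_success: int, n_draw: int) -> np.ndarray:
    """Hypergeometric point probabilities over a support vector, via gammaln."""
    from scipy.special import gammaln

    def log_choose(total, taken):
        return (
            gammaln(total + 1) - gammaln(taken + 1) - gammaln(total - taken + 1)
        )

    log_pmf = (
        log_choose(n_success, k)
        + log_choose(n - n_success, n_draw - k)
        - log_choose(n, n_draw)
    )
    return np.exp(log_pmf)


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value by point-probability summation.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose point probability is <= that of the observed table (within
    relative tolerance :data:`POINT_PROB_RTOL`).  A zero row or column margin
    makes the table degenerate: no association is testable and p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = _hypergeom_pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + POINT_PROB_RTOL)].sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Quantile normalization


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common per-rank-mean distribution.

    Each column keeps its within-column rank order; rank r receives the mean
    of the r-th smallest values across columns.  Ties within a column get the
    average of the target values over the tied ranks.  Requires >= 2 columns.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    if matrix.isna().any().any():
        raise ValueError("matrix must not contain missing values")
    arr = matrix.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="mergesort")
    target = np.take_along_axis(arr, order, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    n = arr.shape[0]
    ranks = np.empty(n, dtype=np.int64)
    for j in range(arr.shape[1]):
        col_order = order[:, j]
        ranks[col_order] = np.arange(n)
        out[:, j] = target[ranks]
        # average target values across tied input ranks
        col = arr[:, j]
        sorted_col = col[col_order]
        tie_starts = np.flatnonzero(np.r_[True, sorted_col[1:] != sorted_col[:-1]])
        tie_ends = np.r_[tie_starts[1:], n]
        for s, e in zip(tie_starts, tie_ends):
            if e - s > 1:
                out[col_order[s:e], j] = target[s:e].mean()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# Median polish


@dataclass(frozen=True)
class MedianPolishResult:
    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return (
            self.overall
            + self.row_effects[:, None]
            + self.col_effects[None, :]
            + self.residuals
        )


def median_polish(
    matrix, max_iter: int = 10, tol: float = 1e-6
) -> MedianPolishResult:
    """Tukey median polish of a two-way table, row sweeps first.

    Alternately removes row and column medians until the absolute change in
    the sum of |residuals| drops below ``tol`` or ``max_iter`` sweeps have
    run.  overall + row_i + col_j + residual_ij reconstructs the input.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    resid = np.array(matrix, dtype=float)
    if resid.ndim != 2 or resid.size == 0:
        raise ValueError("median polish needs a non-empty 2-D matrix")
    nrow, ncol = resid.shape
    overall = 0.0
    row = np.zeros(nrow)
    col = np.zeros(ncol)
    old_sum = np.abs(resid).sum()
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        resid -= rmed[:, None]
        row += rmed
        delta = np.median(col)
        col -= delta
        overall += delta

        cmed = np.median(resid, axis=0)
        resid -= cmed[None, :]
        col += cmed
        delta = np.median(row)
        row -= delta
        overall += delta

        new_sum = np.abs(resid).sum()
        if abs(new_sum - old_sum) < tol:
            break
        old_sum = new_sum
    return MedianPolishResult(float(overall), row, col, resid)


def rma_summarize(
    probe_matrix: pd.DataFrame, gene_of_probe: pd.Series
) -> pd.DataFrame:
    """Quantile-normalize probe columns, then median-polish per gene.

    ``probe_matrix`` is probes x samples (log2 scale); ``gene_of_probe`` maps
    each probe (index entry) to its gene.  Returns a gene x sample matrix of
    summarized expression: overall + sample effect from the per-gene polish.
    Single-probe genes pass through normalization unchanged.
    """
    normalized = quantile_normalize(probe_matrix)
    genes = gene_of_probe.reindex(probe_matrix.index)
    if genes.isna().any():
        missing = genes.index[genes.isna()][0]
        raise ValueError(f"probe {missing!r} has no gene assignment")
    rows = {}
    for gene, block in normalized.groupby(genes, sort=False):
        fit = median_polish(block.to_numpy())
        rows[gene] = fit.overall + fit.col_effects
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=probe_matrix.columns
    )
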