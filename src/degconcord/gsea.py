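"""Pre-ranked gene set enrichment with a gene-permutation null.

Genes are ordered by a per-gene ranking statistic (e.g. the Wald stat of a
count model or a moderated t).  For a gene set, a running sum walks down the
ranking: it rises by |stat|^w / sum of |stat|^w over the set's members at
each hit and falls by 1/(N - N_hits) at each miss.  The enrichment score
(ES) is the signed extremum of that walk.  The null distribution comes from
gene-label permutations that preserve set size; the normalized enrichment
score (NES) divides the observed ES by the mean |ES| of the same-sign
permutations, and nominal permutation p-values are BH-adjusted across sets.

Because only per-gene statistics reach this pipeline (no sample-level
expression), phenotype permutation is not available and gene permutation is
the null of record.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import GeneSetCollection
from .stats_core import bh_adjust

__all__ = [
    "GseaResult",
    "CrossPlatformGsea",
    "preranked_es",
    "gsea_permutation",
    "cross_platform_gsea",
    "results_to_frame",
]


# ---------------------------------------------------------------------------
# Enrichment score


def _es_from_positions(
    weights: np.ndarray, positions: np.ndarray, n_genes: int
) -> np.ndarray:
    """ES for each row of hit positions (sorted ascending, 0-based).

    ``weights`` is the |stat|^w vector over the sorted ranking; the running
    sum only changes slope at hits, so its extrema are attained immediately
    after a hit (candidates for the maximum) or just before one and at the
    end (candidates for the minimum).  Vectorized over permutations.
    """
    pos = np.atleast_2d(positions)
    n_perm, k = pos.shape
    miss_step = 1.0 / (n_genes - k)
    hit_w = weights[pos]
    totals = hit_w.sum(axis=1, keepdims=True)
    # all-zero hit weights degenerate to equal increments
    flat = totals[:, 0] == 0
    if flat.any():
        hit_w = hit_w.copy()
        hit_w[flat] = 1.0
        totals = hit_w.sum(axis=1, keepdims=True)
    cum_hits = np.cumsum(hit_w, axis=1) / totals
    misses_before = pos - np.arange(k)
    after = cum_hits - misses_before * miss_step
    before = np.concatenate(
        [np.zeros((n_perm, 1)), cum_hits[:, :-1]], axis=1
    ) - misses_before * miss_step
    top = after.max(axis=1)
    bottom = np.minimum(before.min(axis=1), 0.0)  # walk ends at 0
    # prefer the positive extremum on |max| == |min| ties (within float noise)
    es = np.where(top + bottom >= -1e-12, top, bottom)
    return np.clip(es, -1.0, 1.0)


def _sorted_ranking(ranking: pd.Series) -> tuple[pd.Index, np.ndarray]:
    stats = ranking.dropna()
    # descending stat; gene id breaks ties for a reproducible order
    order = sorted(stats.index, key=lambda g: (-stats[g], g))
    idx = pd.Index(order)
    return idx, stats[idx].to_numpy(dtype=float)


def preranked_es(
    ranking: pd.Series,
    gene_set,
    weight_exponent: float = 1.0,
) -> float:
    """Enrichment score of one gene set against a ranking statistic.

    ``ranking`` maps gene id -> statistic (sorted internally, descending).
    An empty intersection with the ranking or a set covering the whole
    ranking is an error.
    """
    genes, stats = _sorted_ranking(ranking)
    members = frozenset(gene_set) & frozenset(genes)
    if not members:
        raise ValueError("set not represented in the ranking")
    if len(members) == len(genes):
        raise ValueError("degenerate set: covers the entire ranking")
    weights = np.abs(stats) ** weight_exponent
    positions = np.sort([genes.get_loc(g) for g in members])
    return float(_es_from_positions(weights, np.asarray(positions), len(genes))[0])


# ---------------------------------------------------------------------------
# Permutation testing


@dataclass(frozen=True)
class GseaResult:
    name: str
    es: float
    nes: float
    nominal_p: float
    adj_p: float
    size: int


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.name,
                "size": r.size,
                "es": r.es,
                "nes": r.nes,
                "nominal_p": r.nominal_p,
                "adj_p": r.adj_p,
            }
            for r in results
        ]
    )


def _sample_positions(
    rng: np.random.Generator, n_genes: int, size: int, n_perm: int
) -> np.ndarray:
    """n_perm random size-subsets of range(n_genes), rows sorted ascending."""
    out = np.empty((n_perm, size), dtype=np.int64)
    chunk = max(1, min(n_perm, int(2e6) // max(n_genes, 1)))
    done = 0
    while done < n_perm:
        take = min(chunk, n_perm - done)
        keys = rng.random((take, n_genes))
        part = np.argpartition(keys, size - 1, axis=1)[:, :size]
        out[done : done + take] = np.sort(part, axis=1)
        done += take
    return out


def gsea_permutation(
    ranking_stats: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    weight_exponent: float = 1.0,
    min_size: int = 3,
    max_size: int = 5000,
) -> list[GseaResult]:
    """ES/NES/p for every gene set under a gene-label permutation null.

    For each set, ``n_perm`` random same-size gene subsets give a null ES
    sample.  nominal_p = (1 + #{|ES_perm| >= |ES|, same sign}) /
    (1 + #{same-sign permutations}); NES = ES / mean |ES_perm| over the
    same-sign permutations; adj_p is BH across the emitted sets.  Sets whose
    intersection with the ranking falls outside [min_size, max_size] are
    skipped with a warning.  Deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes, stats = _sorted_ranking(ranking_stats)
    n_genes = len(genes)
    weights = np.abs(stats) ** weight_exponent
    loc = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    null_cache: dict[int, np.ndarray] = {}
    names, es_values, nes_values, p_values, sizes = [], [], [], [], []
    for name in sets.names():
        members = sets[name] & frozenset(loc)
        k = len(members)
        if k < min_size or k > max_size or k >= n_genes:
            _warnings.warn(
                f"gene set {name!r}: size {k} after intersection outside "
                f"[{min_size}, {max_size}], skipped",
                stacklevel=2,
            )
            continue
        positions = np.sort(np.fromiter((loc[g] for g in members), dtype=np.int64))
        es = float(_es_from_positions(weights, positions, n_genes)[0])
        if k not in null_cache:
            perm_pos = _sample_positions(rng, n_genes, k, n_perm)
            null_cache[k] = _es_from_positions(weights, perm_pos, n_genes)
        null_es = null_cache[k]
        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        n_same = int(same_sign.sum())
        n_extreme = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
        nominal_p = (1 + n_extreme) / (1 + n_same)
        mean_abs = np.abs(null_es[same_sign]).mean() if n_same else np.nan
        nes = es / mean_abs if n_same and mean_abs > 0 else np.nan
        names.append(name)
        es_values.append(es)
        nes_values.append(nes)
        p_values.append(nominal_p)
        sizes.append(k)

    adj = bh_adjust(p_values) if names else np.array([])
    results = [
        GseaResult(name, es, nes, p, float(ap), size)
        for name, es, nes, p, ap, size in zip(
            names, es_values, nes_values, p_values, adj, sizes
        )
    ]
    results.sort(key=lambda r: (-(r.nes if np.isfinite(r.nes) else -np.inf), r.name))
    return results


# ---------------------------------------------------------------------------
# Cross-platform comparison


@dataclass(frozen=True)
class CrossPlatformGsea:
    """Shared significant sets between two platforms, by NES sign pair."""

    shared: pd.DataFrame  # columns: set_name, nes_A, nes_B
    concordant_positive: int
    concordant_negative: int
    contradictory: int


def cross_platform_gsea(
    results_a, results_b, alpha: float = 0.05
) -> CrossPlatformGsea:
    """Classify sets significant on both platforms by their NES sign pair."""
    by_name_a = {r.name: r for r in results_a}
    by_name_b = {r.name: r for r in results_b}
    rows = []
    for name in sorted(set(by_name_a) & set(by_name_b)):
        ra, rb = by_name_a[name], by_name_b[name]
        if ra.adj_p < alpha and rb.adj_p < alpha:
            rows.append({"set_name": name, "nes_A": ra.nes, "nes_B": rb.nes})
    shared = pd.DataFrame(rows, columns=["set_name", "nes_A", "nes_B"])
    pos = int(((shared["nes_A"] > 0) & (shared["nes_B"] > 0)).sum())
    neg = int(((shared["nes_A"] < 0) & (shared["nes_B"] < 0)).sum())
    return CrossPlatformGsea(
        shared=shared,
        concordant_positive=pos,
        concordant_negative=neg,
        contradictory=len(shared) - pos - neg,
    )
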