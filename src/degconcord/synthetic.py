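"""Synthetic paired-platform, multi-time-point DE data with ground truth.

The generator emulates the statistical structure the concordance and
dynamics analyses assume, so every pipeline stage can be exercised without
external downloads:

* a latent per-gene regulation state over {U, D, N} that evolves across
  three time points as a Markov chain (rapid early upregulation followed by
  near-complete transient adaptation, the hallmark of short-term
  hypergravity response);
* a shared true log2 effect per regulated gene (truncated normal, with a
  heavier downregulation tail) observed by two platforms: RNA-Seq sees the
  effect plus noise, the microarray sees an attenuated, shifted copy plus
  noise (fold-change compression), and truly upregulated genes can drop out
  of the microarray entirely (missing adjusted p);
* chromosome assignment proportional to per-chromosome observable gene
  counts, with one chromosome's DEG odds multiplied to plant an enrichment;
* biotype labels and gene-set collections with optional planted signal.

Two modes separate combinatorial from statistical testing: ``true_calls``
emits the latent Markov states directly as noise-free regulation calls,
while the full tables carry logFC -> z -> p -> BH-adjusted p per platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import (
    DOWN,
    NS,
    UP,
    DEGTable,
    GeneSetCollection,
    RegulationCalls,
)
from .stats_core import bh_adjust

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SimulatedStudy",
    "simulate_paired_study",
    "simulate_probe_matrix",
    "make_gene_sets",
    "true_calls",
    "fully_transient_config",
    "null_config",
]

STATES = ("U", "D", "N")
PLATFORMS = ("rnaseq", "microarray")

# Approximate relative numbers of annotated genes per human chromosome,
# used to spread observable genes when no explicit plan is given.
_HUMAN_CHROMOSOME_WEIGHTS = {
    "1": 2000, "2": 1300, "3": 1100, "4": 760, "5": 900, "6": 1000,
    "7": 950, "8": 700, "9": 800, "10": 750, "11": 1300, "12": 1050,
    "13": 330, "14": 650, "15": 620, "16": 870, "17": 1200, "18": 280,
    "19": 1400, "20": 550, "21": 230, "22": 450, "X": 850, "Y": 60,
    "MT": 13,
}

_DEFAULT_BIOTYPE_PROBS = {
    "protein_coding": 0.76,
    "lncRNA": 0.14,
    "processed_pseudogene": 0.06,
    "snRNA": 0.025,
    "miRNA": 0.015,
}

# Default Markov structure: ~5% of genes respond immediately (mostly up),
# regulated genes persist at the second time point with probability 0.89
# while a delayed pool switches on, and by the third time point every
# regulated state has either reverted to N or counter-regulated — the
# transient-response design.  Rows/columns ordered U, D, N.
_DEFAULT_INITIAL = (0.049, 0.004, 0.947)
_DEFAULT_T1_T2 = (
    (0.89, 0.00, 0.11),
    (0.00, 0.89, 0.11),
    (0.185, 0.183, 0.632),
)
_DEFAULT_T2_T3 = (
    (0.00, 0.33, 0.67),
    (0.00, 0.00, 1.00),
    (0.00, 0.00, 1.00),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters for the paired-platform generator.

    Effects are on the log2 fold-change scale; ``se_rnaseq``/``se_micro``
    are per-platform standard errors of the observed logFC;
    ``attenuation_micro`` in (0, 1] compresses microarray fold changes and
    ``dropout_up_micro`` is the probability that a truly upregulated gene is
    unobservable on the microarray.
    """

    n_genes: int = 20000
    timepoints: int = 3
    initial_state_probs: tuple = _DEFAULT_INITIAL
    transition_t1_t2: tuple = _DEFAULT_T1_T2
    transition_t2_t3: tuple = _DEFAULT_T2_T3
    effect_mean_up: float = 1.0
    effect_mean_down: float = 1.5
    effect_sd: float = 0.5
    se_rnaseq: float = 0.15
    se_micro: float = 0.25
    attenuation_micro: float = 0.7
    dropout_up_micro: float = 0.3
    shift_micro: float = 0.1
    # platforms share the same standardized noise draws (degenerate mode in
    # which equal SEs plus attenuation 1 / shift 0 make the tables identical)
    shared_noise: bool = False
    chromosomes: tuple | None = None  # ((label, n_observable), ...)
    enriched_chromosome: str | None = "19"
    enrichment_multiplier: float = 3.0
    biotype_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BIOTYPE_PROBS)
    )
    n_gene_sets: int = 50
    set_size_range: tuple = (10, 60)
    n_planted_sets: int = 3
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_genes < 1:
            problems.append("n_genes must be >= 1")
        if self.timepoints not in (2, 3):
            problems.append("timepoints must be 2 or 3")
        for name, vec in [("initial_state_probs", self.initial_state_probs)]:
            if len(vec) != 3 or abs(sum(vec) - 1.0) > 1e-9 or min(vec) < 0:
                problems.append(f"{name} must be 3 non-negative probs summing to 1")
        for name, mat in [
            ("transition_t1_t2", self.transition_t1_t2),
            ("transition_t2_t3", self.transition_t2_t3),
        ]:
            arr = np.asarray(mat, dtype=float)
            if arr.shape != (3, 3) or (arr < 0).any() or (
                np.abs(arr.sum(axis=1) - 1.0) > 1e-9
            ).any():
                problems.append(f"{name} must be a 3x3 row-stochastic matrix")
        if not 0 < self.attenuation_micro <= 1:
            problems.append("attenuation_micro must be in (0, 1]")
        if not 0 <= self.dropout_up_micro <= 1:
            problems.append("dropout_up_micro must be a probability")
        if self.effect_sd <= 0 or self.se_rnaseq <= 0 or self.se_micro <= 0:
            problems.append("effect_sd and platform SEs must be positive")
        bp = sum(self.biotype_probs.values())
        if abs(bp - 1.0) > 1e-9 or min(self.biotype_probs.values()) < 0:
            problems.append("biotype_probs must sum to 1 and be non-negative")
        if self.set_size_range[0] < 1 or self.set_size_range[0] > self.set_size_range[1]:
            problems.append("set_size_range must be a non-empty (lo, hi) with lo >= 1")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))

    def chromosome_plan(self) -> tuple:
        """Explicit (label, n_observable) plan, scaled to n_genes by default."""
        if self.chromosomes is not None:
            return tuple(self.chromosomes)
        weights = np.array(list(_HUMAN_CHROMOSOME_WEIGHTS.values()), dtype=float)
        sizes = np.floor(weights / weights.sum() * self.n_genes).astype(int)
        sizes[0] += self.n_genes - sizes.sum()  # remainder onto chr1
        return tuple(zip(_HUMAN_CHROMOSOME_WEIGHTS.keys(), (int(s) for s in sizes)))


def fully_transient_config(**overrides) -> SyntheticConfig:
    """The default design: all regulated states adapt by the third time point."""
    return replace(SyntheticConfig(), **overrides)


def null_config(**overrides) -> SyntheticConfig:
    """No true regulation at any time point (pure-null tables)."""
    identity = ((1.0, 0, 0), (0, 1.0, 0), (0, 0, 1.0))
    cfg = SyntheticConfig(
        initial_state_probs=(0.0, 0.0, 1.0),
        transition_t1_t2=identity,
        transition_t2_t3=identity,
        enriched_chromosome=None,
        n_planted_sets=0,
    )
    return replace(cfg, **overrides)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth: per-gene states/effects per time point plus annotation."""

    genes: pd.DataFrame  # state_t*, effect_t*, chromosome, biotype
    timepoints: int

    def state(self, timepoint: int) -> pd.Series:
        return self.genes[f"state_t{timepoint}"]

    def effect(self, timepoint: int) -> pd.Series:
        return self.genes[f"effect_t{timepoint}"]


@dataclass(frozen=True)
class SimulatedStudy:
    tables: dict  # (platform, timepoint) -> DEGTable
    truth: SyntheticTruth
    config: SyntheticConfig

    def table(self, platform: str, timepoint: int) -> DEGTable:
        return self.tables[(platform, timepoint)]


def _draw_states(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_genes, timepoints) array of state indices into STATES."""
    n = cfg.n_genes
    states = np.empty((n, cfg.timepoints), dtype=np.int64)
    states[:, 0] = rng.choice(3, size=n, p=np.asarray(cfg.initial_state_probs))
    matrices = [np.asarray(cfg.transition_t1_t2), np.asarray(cfg.transition_t2_t3)]
    for t in range(1, cfg.timepoints):
        mat = matrices[t - 1]
        prev = states[:, t - 1]
        u = rng.random(n)
        cdf = np.cumsum(mat, axis=1)
        states[:, t] = (u[:, None] > cdf[prev]).sum(axis=1)
    return states


def _draw_effects(
    cfg: SyntheticConfig, states: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """True log2 effects: 0 for N, sign-truncated normals for U and D."""
    effects = np.zeros_like(states, dtype=float)
    for code, mean, sign in ((0, cfg.effect_mean_up, 1.0), (1, cfg.effect_mean_down, -1.0)):
        mask = states == code
        n = int(mask.sum())
        if n:
            a = (0.0 - mean) / cfg.effect_sd  # truncate at zero, keep positive
            draws = sps.truncnorm.rvs(
                a, np.inf, loc=mean, scale=cfg.effect_sd, size=n, random_state=rng
            )
            effects[mask] = sign * draws
    return effects


def _assign_chromosomes(
    cfg: SyntheticConfig, deg_at_t1: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    plan = cfg.chromosome_plan()
    labels = np.array([label for label, _ in plan])
    base = np.array([max(size, 0) for _, size in plan], dtype=float)
    if base.sum() <= 0:
        raise ValueError("chromosome plan has no observable genes")
    base = base / base.sum()
    boosted = base.copy()
    if cfg.enriched_chromosome is not None:
        idx = np.flatnonzero(labels == cfg.enriched_chromosome)
        if idx.size == 0:
            raise ValueError(
                f"enriched chromosome {cfg.enriched_chromosome!r} not in plan"
            )
        boosted[idx[0]] *= cfg.enrichment_multiplier
        boosted = boosted / boosted.sum()
    out = np.empty(len(deg_at_t1), dtype=object)
    n_deg = int(deg_at_t1.sum())
    out[deg_at_t1] = rng.choice(labels, size=n_deg, p=boosted)
    out[~deg_at_t1] = rng.choice(labels, size=len(deg_at_t1) - n_deg, p=base)
    return out


def simulate_paired_study(
    cfg: SyntheticConfig, seed: int | None = None
) -> SimulatedStudy:
    """Generate per-platform, per-time-point DE tables plus ground truth.

    Per gene and time point the latent state comes from the Markov chain and
    the true effect from the sign-truncated normals; RNA-Seq observes
    effect + noise, the microarray attenuation * effect + shift + noise.
    z = logFC / se gives a two-sided normal p, BH-adjusted within each
    table; microarray adjusted p of dropped-out true-U genes is missing.
    Deterministic for a fixed seed (``seed`` overrides ``cfg.seed``).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_genes
    gene_ids = pd.Index([f"G{i:06d}" for i in range(n)], name="gene_id")

    states = _draw_states(cfg, rng)
    effects = _draw_effects(cfg, states, rng)
    deg_t1 = states[:, 0] != 2
    chromosomes = _assign_chromosomes(cfg, deg_t1, rng)
    biotype_labels = np.array(list(cfg.biotype_probs))
    biotype_p = np.array(list(cfg.biotype_probs.values()), dtype=float)
    biotypes = rng.choice(biotype_labels, size=n, p=biotype_p / biotype_p.sum())

    truth_cols = {}
    for t in range(cfg.timepoints):
        truth_cols[f"state_t{t + 1}"] = np.array(STATES)[states[:, t]]
        truth_cols[f"effect_t{t + 1}"] = effects[:, t]
    truth_cols["chromosome"] = chromosomes
    truth_cols["biotype"] = biotypes
    truth = SyntheticTruth(pd.DataFrame(truth_cols, index=gene_ids), cfg.timepoints)

    tables: dict = {}
    for t in range(cfg.timepoints):
        delta = effects[:, t]
        eps = {p: rng.standard_normal(n) for p in PLATFORMS}
        if cfg.shared_noise:
            eps["microarray"] = eps["rnaseq"]
        for platform in PLATFORMS:
            if platform == "rnaseq":
                se = cfg.se_rnaseq
                fc = delta + se * eps[platform]
            else:
                se = cfg.se_micro
                fc = (
                    cfg.attenuation_micro * delta
                    + cfg.shift_micro
                    + se * eps[platform]
                )
            z = fc / se
            p = 2.0 * sps.norm.sf(np.abs(z))
            if platform == "microarray" and cfg.dropout_up_micro > 0:
                drop = (states[:, t] == 0) & (rng.random(n) < cfg.dropout_up_micro)
                p = p.copy()
                p[drop] = np.nan
            adj = bh_adjust(p)
            frame = pd.DataFrame(
                {
                    "log2fc": fc,
                    "pvalue": p,
                    "adj_pvalue": adj,
                    "chromosome": pd.array(chromosomes, dtype="string"),
                    "biotype": pd.array(biotypes, dtype="string"),
                    "rank_stat": z,
                },
                index=gene_ids,
            )
            tables[(platform, t + 1)] = DEGTable(frame)
    return SimulatedStudy(tables, truth, cfg)


def true_calls(truth: SyntheticTruth, timepoint: int, alpha: float = 0.05) -> RegulationCalls:
    """Noise-free regulation calls straight from the latent Markov states."""
    mapping = {"U": UP, "D": DOWN, "N": NS}
    return RegulationCalls(truth.state(timepoint).map(mapping), alpha)


def recover_attenuation(study: SimulatedStudy) -> float:
    """Estimate the microarray fold-change compression from a simulated study.

    Rank-free regression of microarray log2fc on RNA-Seq log2fc over the
    true DEGs of every time point, with the regressor's known noise variance
    subtracted (errors-in-variables correction); pooling time points uses
    the large delayed-response pool, not just the small initial one.
    """
    cfg = study.config
    xs, ys = [], []
    for t in range(1, cfg.timepoints + 1):
        deg = (study.truth.state(t) != "N").to_numpy()
        xs.append(study.table("rnaseq", t).data["log2fc"].to_numpy()[deg])
        ys.append(study.table("microarray", t).data["log2fc"].to_numpy()[deg])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(x) < 3:
        raise ValueError("too few true DEGs to estimate attenuation")
    cov = np.cov(x, y)
    return float(cov[0, 1] / (cov[0, 0] - cfg.se_rnaseq**2))


# ---------------------------------------------------------------------------
# Probe-level matrix (fixture for the RMA-style summarization)


def simulate_probe_matrix(
    cfg: SyntheticConfig,
    n_samples: int,
    n_probes_per_gene: int,
    affinity_sd: float = 0.5,
    sample_shift_sd: float = 0.3,
    noise_sd: float = 0.2,
    effect_mean: float = 7.0,
    effect_sd: float = 2.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Probe intensities = gene effect + probe affinity + sample shift + noise.

    Returns (matrix probes x samples, gene_of_probe, true gene effects).
    """
    if n_samples < 2:
        raise ValueError("need >= 2 samples")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_genes
    gene_ids = [f"G{i:06d}" for i in range(n)]
    gene_effect = rng.normal(effect_mean, effect_sd, size=n)
    affinities = rng.normal(0.0, affinity_sd, size=(n, n_probes_per_gene))
    shifts = rng.normal(0.0, sample_shift_sd, size=n_samples)
    noise = rng.normal(0.0, noise_sd, size=(n * n_probes_per_gene, n_samples))
    intensity = (
        np.repeat(gene_effect, n_probes_per_gene)[:, None]
        + affinities.reshape(-1)[:, None]
        + shifts[None, :]
        + noise
    )
    probe_ids = [
        f"{g}_p{j}" for g in gene_ids for j in range(n_probes_per_gene)
    ]
    matrix = pd.DataFrame(
        intensity,
        index=pd.Index(probe_ids, name="probe_id"),
        columns=[f"S{j}" for j in range(n_samples)],
    )
    gene_of_probe = pd.Series(np.repeat(gene_ids, n_probes_per_gene), index=matrix.index)
    effects = pd.Series(gene_effect, index=pd.Index(gene_ids, name="gene_id"))
    return matrix, gene_of_probe, effects


# ---------------------------------------------------------------------------
# Gene sets


def make_gene_sets(
    truth: SyntheticTruth,
    cfg: SyntheticConfig,
    planted_direction: str = "U",
    planted_timepoint: int = 1,
    seed: int | None = None,
) -> tuple[GeneSetCollection, tuple]:
    """Random gene sets, the first ``n_planted_sets`` drawn from true DEGs.

    Planted sets sample exclusively from genes whose latent state at
    ``planted_timepoint`` equals ``planted_direction``; the rest are drawn
    uniformly from all genes.  Returns the collection and the tuple of
    planted set names.  Raises if the true-DEG pool cannot fill a set.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    all_genes = np.asarray(truth.genes.index)
    pool = np.asarray(
        truth.genes.index[truth.state(planted_timepoint) == planted_direction]
    )
    lo, hi = cfg.set_size_range
    sets: dict[str, frozenset] = {}
    planted: list[str] = []
    for i in range(cfg.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        if i < cfg.n_planted_sets:
            if len(pool) < size:
                raise ValueError(
                    f"not enough true-{planted_direction} genes ({len(pool)}) "
                    f"to fill a planted set of size {size}"
                )
            members = rng.choice(pool, size=size, replace=False)
            name = f"PLANTED_{planted_direction}_{i + 1:03d}"
            planted.append(name)
        else:
            members = rng.choice(all_genes, size=size, replace=False)
            name = f"RANDOM_{i + 1:03d}"
        sets[name] = frozenset(str(g) for g in members)
    return GeneSetCollection(sets), tuple(planted)
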