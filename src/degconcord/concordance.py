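"""Pairwise cross-platform comparison of differential-expression tables.

Covers the gene-level agreement questions asked when the same samples are
profiled on two platforms (e.g. microarray vs RNA-Seq): regulation calls,
directional overlap counts (the upset-style bookkeeping that can expose
contradictory directions, which a Venn diagram cannot), the set-inclusion
sweep that halves one platform's significance cutoff stepwise, Spearman
concordance of fold changes, consensus DEG sets and the top-N
average-fold-change tables, and gene-level differential-exon-usage overlap.

Call conventions: a gene is UP iff adj_p < alpha and log2fc > 0, DOWN iff
adj_p < alpha and log2fc < 0 (strict inequalities and strict sign; a gene at
exactly adj_p == alpha or log2fc == 0 is NS), UNOBSERVED iff adj_p is
missing.  Genes absent from one table are UNOBSERVED there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import (
    DOWN,
    NS,
    UNOBSERVED,
    UP,
    DEGTable,
    DEUList,
    RegulationCalls,
    shared_universe,
)

__all__ = [
    "DirectionalOverlap",
    "InclusionCurve",
    "ConsensusSet",
    "DEUOverlap",
    "classify_regulation",
    "directional_overlap",
    "inclusion_sweep",
    "spearman_concordance",
    "consensus_degs",
    "rank_by_average_fc",
    "deu_overlap",
]


def classify_regulation(table: DEGTable, alpha: float = 0.05) -> RegulationCalls:
    """Assign UP/DOWN/NS/UNOBSERVED calls from adjusted p and log2fc sign."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    adj = table.data["adj_pvalue"]
    fc = table.data["log2fc"]
    calls = pd.Series(NS, index=table.gene_ids, dtype=object)
    sig = adj < alpha
    calls[sig & (fc > 0)] = UP
    calls[sig & (fc < 0)] = DOWN
    calls[adj.isna()] = UNOBSERVED
    return RegulationCalls(calls, alpha)


# ---------------------------------------------------------------------------
# Directional overlap (upset-style accounting)


@dataclass(frozen=True)
class DirectionalOverlap:
    """Intersection counts between two call sets over their gene union.

    The first eight counts partition the genes called UP or DOWN in at least
    one set; ``neither`` holds the remaining (NS/UNOBSERVED on both sides)
    genes.  "Detected in the other set" is exposed in two senses: significant
    in any direction (``*_any``) and with matching direction (``*_same``).
    """

    both_up: int
    both_down: int
    contradictory_AupBdown: int
    contradictory_AdownBup: int
    A_only_up: int
    A_only_down: int
    B_only_up: int
    B_only_down: int
    neither: int
    fraction_A_in_B_any: dict = field(default_factory=dict)
    fraction_A_in_B_same: dict = field(default_factory=dict)
    fraction_B_in_A_any: dict = field(default_factory=dict)
    fraction_B_in_A_same: dict = field(default_factory=dict)

    @property
    def n_either(self) -> int:
        return (
            self.both_up
            + self.both_down
            + self.contradictory_AupBdown
            + self.contradictory_AdownBup
            + self.A_only_up
            + self.A_only_down
            + self.B_only_up
            + self.B_only_down
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("both_up", self.both_up),
            ("both_down", self.both_down),
            ("contradictory_AupBdown", self.contradictory_AupBdown),
            ("contradictory_AdownBup", self.contradictory_AdownBup),
            ("A_only_up", self.A_only_up),
            ("A_only_down", self.A_only_down),
            ("B_only_up", self.B_only_up),
            ("B_only_down", self.B_only_down),
            ("neither", self.neither),
        ]
        return pd.DataFrame(rows, columns=["category", "count"])


def _fraction(numer: int, denom: int) -> float | None:
    return None if denom == 0 else numer / denom


def directional_overlap(
    calls_a: RegulationCalls, calls_b: RegulationCalls
) -> DirectionalOverlap:
    universe = shared_universe(calls_a, calls_b)
    a = calls_a.reindex(universe).calls
    b = calls_b.reindex(universe).calls
    a_sig = a.isin([UP, DOWN])
    b_sig = b.isin([UP, DOWN])

    counts = dict(
        both_up=int(((a == UP) & (b == UP)).sum()),
        both_down=int(((a == DOWN) & (b == DOWN)).sum()),
        contradictory_AupBdown=int(((a == UP) & (b == DOWN)).sum()),
        contradictory_AdownBup=int(((a == DOWN) & (b == UP)).sum()),
        A_only_up=int(((a == UP) & ~b_sig).sum()),
        A_only_down=int(((a == DOWN) & ~b_sig).sum()),
        B_only_up=int(((b == UP) & ~a_sig).sum()),
        B_only_down=int(((b == DOWN) & ~a_sig).sum()),
        neither=int((~a_sig & ~b_sig).sum()),
    )
    frac_a_any, frac_a_same, frac_b_any, frac_b_same = {}, {}, {}, {}
    for d in (UP, DOWN):
        n_a = int((a == d).sum())
        n_b = int((b == d).sum())
        frac_a_any[d] = _fraction(int(((a == d) & b_sig).sum()), n_a)
        frac_a_same[d] = _fraction(int(((a == d) & (b == d)).sum()), n_a)
        frac_b_any[d] = _fraction(int(((b == d) & a_sig).sum()), n_b)
        frac_b_same[d] = _fraction(int(((b == d) & (a == d)).sum()), n_b)
    return DirectionalOverlap(
        **counts,
        fraction_A_in_B_any=frac_a_any,
        fraction_A_in_B_same=frac_a_same,
        fraction_B_in_A_any=frac_b_any,
        fraction_B_in_A_same=frac_b_same,
    )


# ---------------------------------------------------------------------------
# Set-inclusion sweep


@dataclass(frozen=True)
class InclusionCurve:
    """Overlap of significant sets while one cutoff is halved stepwise.

    Row k holds cutoff alpha_fixed / 2**k for the swept table, the fixed and
    swept significant-set sizes, their overlap, and frequency =
    n_overlap / n_swept (NaN when n_swept is 0).
    """

    rows: pd.DataFrame  # columns: cutoff_swept, n_fixed, n_swept, n_overlap, frequency

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


def inclusion_sweep(
    table_a: DEGTable,
    table_b: DEGTable,
    alpha_fixed: float = 0.05,
    n_halvings: int = 4,
    swept: str = "B",
) -> InclusionCurve:
    """Fix one table at ``alpha_fixed``; halve the other's cutoff k times.

    Iteration k = 0..n_halvings uses cutoff alpha_fixed / 2**k for the swept
    table (with the default 0.05 and 4 halvings the final cutoff is 0.003125,
    i.e. 0.0031 at the reported precision).  Significance is any-direction:
    adj_p below the cutoff.
    """
    if n_halvings < 0:
        raise ValueError("n_halvings must be >= 0")
    if swept not in ("A", "B"):
        raise ValueError("swept must be 'A' or 'B'")
    fixed_table, swept_table = (table_b, table_a) if swept == "A" else (table_a, table_b)
    fixed_sig = set(fixed_table.gene_ids[fixed_table.significant(alpha_fixed)])
    swept_adj = swept_table.data["adj_pvalue"]
    records = []
    for k in range(n_halvings + 1):
        cutoff = alpha_fixed / 2**k
        swept_sig = set(swept_adj.index[swept_adj < cutoff])
        overlap = len(fixed_sig & swept_sig)
        records.append(
            {
                "cutoff_swept": cutoff,
                "n_fixed": len(fixed_sig),
                "n_swept": len(swept_sig),
                "n_overlap": overlap,
                "frequency": overlap / len(swept_sig) if swept_sig else np.nan,
            }
        )
    return InclusionCurve(pd.DataFrame.from_records(records))


# ---------------------------------------------------------------------------
# Spearman concordance


def spearman_concordance(
    table_a: DEGTable,
    table_b: DEGTable,
    restrict: str = "all",
    alpha: float = 0.05,
) -> float:
    """Spearman rho of paired log2 fold changes over shared genes.

    ``restrict`` is "all" (every shared gene with a fold change in both
    tables) or "significant_in_both" (adj_p < alpha on both platforms).
    Average ranks are used for ties.  Fewer than 3 shared genes after
    restriction is an error.
    """
    if restrict not in ("all", "significant_in_both"):
        raise ValueError(f"unknown restriction {restrict!r}")
    shared = table_a.gene_ids.intersection(table_b.gene_ids)
    fc_a = table_a.data.loc[shared, "log2fc"]
    fc_b = table_b.data.loc[shared, "log2fc"]
    keep = fc_a.notna() & fc_b.notna()
    if restrict == "significant_in_both":
        keep &= table_a.data.loc[shared, "adj_pvalue"] < alpha
        keep &= table_b.data.loc[shared, "adj_pvalue"] < alpha
    if keep.sum() < 3:
        raise ValueError(
            f"need >= 3 shared genes after restriction, have {int(keep.sum())}"
        )
    rho, _ = sps.spearmanr(fc_a[keep], fc_b[keep])
    return float(rho)


# ---------------------------------------------------------------------------
# Consensus DEGs


@dataclass(frozen=True)
class ConsensusSet:
    """Genes significant with the same fold-change sign on both platforms.

    ``records`` columns: direction, log2fc_A, log2fc_B, avg_log2fc (the
    arithmetic mean of the two log2 fold changes), indexed by gene_id.
    """

    records: pd.DataFrame
    alpha: float = 0.05

    def __len__(self) -> int:
        return len(self.records)

    def direction(self, d: str) -> pd.DataFrame:
        return self.records[self.records["direction"] == d]


def consensus_degs(
    table_a: DEGTable, table_b: DEGTable, alpha: float = 0.05
) -> ConsensusSet:
    shared = table_a.gene_ids.intersection(table_b.gene_ids)
    sub_a = table_a.data.loc[shared]
    sub_b = table_b.data.loc[shared]
    sig = (sub_a["adj_pvalue"] < alpha) & (sub_b["adj_pvalue"] < alpha)
    sign_a = np.sign(sub_a["log2fc"])
    same_sign = (sign_a == np.sign(sub_b["log2fc"])) & (sign_a != 0)
    members = shared[(sig & same_sign).to_numpy()]
    records = pd.DataFrame(
        {
            "direction": np.where(sub_a.loc[members, "log2fc"] > 0, UP, DOWN),
            "log2fc_A": sub_a.loc[members, "log2fc"].to_numpy(),
            "log2fc_B": sub_b.loc[members, "log2fc"].to_numpy(),
        },
        index=pd.Index(members, name="gene_id"),
    )
    records["avg_log2fc"] = (records["log2fc_A"] + records["log2fc_B"]) / 2.0
    return ConsensusSet(records.sort_index(), alpha)


def rank_by_average_fc(
    consensus: ConsensusSet, direction: str, n: int = 21
) -> pd.DataFrame:
    """Top-n consensus genes of one direction by |avg_log2fc|, descending.

    Ties in magnitude break by gene_id ascending; fewer than n rows are
    returned if the direction holds fewer members.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if direction not in (UP, DOWN):
        raise ValueError(f"direction must be UP or DOWN, got {direction!r}")
    sub = consensus.direction(direction).copy()
    sub["_mag"] = sub["avg_log2fc"].abs()
    sub = sub.sort_values(
        by=["_mag", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return sub.drop(columns="_mag").head(n)


# ---------------------------------------------------------------------------
# Differential exon usage overlap


@dataclass(frozen=True)
class DEUOverlap:
    n_A: int
    n_B: int
    n_overlap: int
    fraction_of_B_in_A: float | None


def deu_overlap(
    list_a: DEUList,
    list_b: DEUList,
    cutoff_a: float = 0.05,
    cutoff_b: float = 0.05,
) -> DEUOverlap:
    """Overlap of gene-level DEU calls between two platforms' lists."""
    sig_a = set(list_a.significant(cutoff_a))
    sig_b = set(list_b.significant(cutoff_b))
    n_overlap = len(sig_a & sig_b)
    return DEUOverlap(
        n_A=len(sig_a),
        n_B=len(sig_b),
        n_overlap=n_overlap,
        fraction_of_B_in_A=_fraction(n_overlap, len(sig_b)),
    )
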