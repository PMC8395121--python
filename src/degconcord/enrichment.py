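"""Aggregated-level DEG characterization: biotypes and chromosomes.

Biotype composition tabulates what fraction of the up- and downregulated
genes fall in each gene class (protein_coding, lncRNA, ...), after dropping
biotypes that occur fewer than ``min_biotype_count`` times in the entire
table (rare classes are noise at this resolution).

Chromosomal enrichment asks whether DEGs pile up on particular chromosomes.
Expected counts assume a random distribution of DEGs over observable genes;
two Fisher exact test families per chromosome probe (1) the total DEG count
against the rest of the genome and (2) the up/down ratio against the rest.
Each family is BH-adjusted across chromosomes separately and starred at
adjusted p < 0.05 (*) / < 0.01 (**).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DOWN, UP, DEGTable, RegulationCalls
from .stats_core import ContingencyTable2x2, bh_adjust, fisher_exact_2x2

__all__ = [
    "BiotypeComposition",
    "ChromosomeEnrichment",
    "biotype_composition",
    "chromosome_expected_counts",
    "chromosome_enrichment_tests",
    "CANONICAL_CHROMOSOMES",
]

UNANNOTATED = "unannotated"

CANONICAL_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")


# ---------------------------------------------------------------------------
# Biotype composition


@dataclass(frozen=True)
class BiotypeComposition:
    """Per-direction biotype counts/fractions after low-count filtering."""

    table: pd.DataFrame  # columns: direction, biotype, count, fraction
    filtered_out: tuple
    min_biotype_count: int

    def fraction(self, direction: str, biotype: str) -> float:
        sub = self.table
        hit = sub[(sub["direction"] == direction) & (sub["biotype"] == biotype)]
        return float(hit["fraction"].iloc[0]) if len(hit) else 0.0


def biotype_composition(
    table: DEGTable,
    calls: RegulationCalls,
    min_biotype_count: int = 20,
) -> BiotypeComposition:
    """Biotype breakdown of UP and DOWN genes.

    Occurrence filtering uses the whole table (all genes, not only DEGs):
    biotypes seen fewer than ``min_biotype_count`` times anywhere are dropped
    before the per-direction counting.  Missing biotype labels are grouped
    as "unannotated".
    """
    biotypes = table.data["biotype"].fillna(UNANNOTATED).astype(str)
    occurrence = biotypes.value_counts()
    retained = set(occurrence.index[occurrence >= min_biotype_count])
    filtered_out = tuple(sorted(set(occurrence.index) - retained))

    aligned = calls.reindex(table.gene_ids).calls
    rows = []
    for direction in (UP, DOWN):
        members = biotypes[(aligned == direction) & biotypes.isin(retained)]
        counts = members.value_counts()
        total = int(counts.sum())
        for biotype, count in counts.sort_index().items():
            rows.append(
                {
                    "direction": direction,
                    "biotype": biotype,
                    "count": int(count),
                    "fraction": count / total if total else np.nan,
                }
            )
    frame = pd.DataFrame(rows, columns=["direction", "biotype", "count", "fraction"])
    return BiotypeComposition(frame, filtered_out, min_biotype_count)


# ---------------------------------------------------------------------------
# Chromosome-level accounting


def _normalize_chromosome(label: str) -> str:
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    if label.upper() in ("X", "Y", "MT", "M"):
        return "MT" if label.upper() in ("MT", "M") else label.upper()
    return label


def _per_chromosome_counts(
    table: DEGTable, calls: RegulationCalls, include_other: bool
) -> tuple[pd.DataFrame, list[str]]:
    """Observable/DEG/up/down counts per chromosome, canonical order."""
    warnings: list[str] = []
    chrom = table.data["chromosome"]
    n_missing = int(chrom.isna().sum())
    if n_missing:
        warnings.append(f"{n_missing} genes without chromosome annotation excluded")
    observable = table.observable & chrom.notna()
    labels = chrom[observable].map(_normalize_chromosome)
    aligned = calls.reindex(table.gene_ids).calls[observable]

    canonical = [c for c in CANONICAL_CHROMOSOMES if (labels == c).any()]
    others = sorted(set(labels) - set(CANONICAL_CHROMOSOMES))
    if others and include_other:
        labels = labels.where(~labels.isin(others), "other")
        canonical.append("other")
    elif others:
        warnings.append(
            f"non-canonical contigs excluded from testing: {', '.join(others)}"
        )
        keep = ~labels.isin(others)
        labels, aligned = labels[keep], aligned[keep]

    records = []
    for c in canonical:
        on_c = labels == c
        n_obs = int(on_c.sum())
        if n_obs == 0:
            warnings.append(f"chromosome {c}: 0 observable genes, excluded")
            continue
        sub = aligned[on_c]
        n_up = int((sub == UP).sum())
        n_down = int((sub == DOWN).sum())
        records.append(
            {
                "chromosome": c,
                "n_observable": n_obs,
                "n_deg": n_up + n_down,
                "n_up": n_up,
                "n_down": n_down,
            }
        )
    frame = pd.DataFrame(
        records, columns=["chromosome", "n_observable", "n_deg", "n_up", "n_down"]
    ).set_index("chromosome")
    return frame, warnings


def chromosome_expected_counts(
    table: DEGTable,
    calls: RegulationCalls,
    include_other: bool = False,
) -> pd.DataFrame:
    """Expected DEG counts per chromosome under a random distribution.

    expected_total(c) = N_deg * n_observable(c) / N_observable — the total
    DEG count spread proportionally to each chromosome's share of observable
    (adjusted p not missing) genes.  expected_up(c) = n_deg(c) * N_up /
    (N_up + N_down) — the chromosome's observed DEG count split by the
    global up:down ratio (missing when no gene is UP or DOWN globally).
    """
    counts, _ = _per_chromosome_counts(table, calls, include_other)
    if counts["n_observable"].sum() == 0:
        raise ValueError("no observable genes with chromosome annotation")
    n_deg_total = counts["n_deg"].sum()
    n_up_total = counts["n_up"].sum()
    n_down_total = counts["n_down"].sum()
    out = counts.copy()
    out["expected_total"] = (
        n_deg_total * counts["n_observable"] / counts["n_observable"].sum()
    )
    if n_up_total + n_down_total:
        out["expected_up"] = counts["n_deg"] * n_up_total / (n_up_total + n_down_total)
    else:
        out["expected_up"] = np.nan
    return out[["expected_total", "expected_up"]]


@dataclass(frozen=True)
class ChromosomeEnrichment:
    """Per-chromosome enrichment results with FDR-starred significance.

    ``table`` rows follow natural chromosome order (1..22, X, Y, MT) and
    carry observed/expected counts, the two families' raw and BH-adjusted
    Fisher p-values, the deviation direction, and star labels.
    """

    table: pd.DataFrame
    warnings: tuple = ()
    alpha_star: float = 0.05
    alpha_doublestar: float = 0.01


def _stars(adj_p: float, alpha_star: float, alpha_doublestar: float) -> str:
    if np.isnan(adj_p):
        return ""
    if adj_p < alpha_doublestar:
        return "**"
    if adj_p < alpha_star:
        return "*"
    return ""


def chromosome_enrichment_tests(
    table: DEGTable,
    calls: RegulationCalls,
    alpha_star: float = 0.05,
    alpha_doublestar: float = 0.01,
    include_other: bool = False,
) -> ChromosomeEnrichment:
    """Two Fisher exact test families per chromosome, BH-adjusted per family.

    Family 1 (total DEG distribution) tests, for each chromosome c,
    [[n_deg(c), n_obs(c) - n_deg(c)], [N_deg - n_deg(c), rest]] over the
    observable-gene universe.  Family 2 (direction ratio) tests
    [[n_up(c), n_down(c)], [N_up - n_up(c), N_down - n_down(c)]], each
    chromosome against its complement.  Stars come from the FDR-adjusted
    p-values of each family at ``alpha_star`` / ``alpha_doublestar``.
    """
    counts, warnings = _per_chromosome_counts(table, calls, include_other)
    if len(counts) < 2:
        raise ValueError("chromosome enrichment needs >= 2 chromosomes")
    n_obs_total = int(counts["n_observable"].sum())
    n_deg_total = int(counts["n_deg"].sum())
    n_up_total = int(counts["n_up"].sum())
    n_down_total = int(counts["n_down"].sum())

    expected = chromosome_expected_counts(table, calls, include_other)

    p_total, p_updown = [], []
    for c, row in counts.iterrows():
        t1 = ContingencyTable2x2(
            a=int(row["n_deg"]),
            b=int(row["n_observable"] - row["n_deg"]),
            c=int(n_deg_total - row["n_deg"]),
            d=int((n_obs_total - row["n_observable"]) - (n_deg_total - row["n_deg"])),
        )
        p_total.append(fisher_exact_2x2(t1))
        rest_up = n_up_total - int(row["n_up"])
        rest_down = n_down_total - int(row["n_down"])
        if row["n_up"] + row["n_down"] + rest_up + rest_down == 0:
            p_updown.append(np.nan)
        else:
            t2 = ContingencyTable2x2(
                a=int(row["n_up"]), b=int(row["n_down"]), c=rest_up, d=rest_down
            )
            p_updown.append(fisher_exact_2x2(t2))

    adj_total = bh_adjust(p_total)
    adj_updown = bh_adjust(p_updown)

    out = counts.copy()
    out["expected_total"] = expected["expected_total"]
    out["expected_up"] = expected["expected_up"]
    out["p_total"] = p_total
    out["p_updown"] = p_updown
    out["adj_p_total"] = adj_total
    out["adj_p_updown"] = adj_updown
    deviation = np.where(
        out["n_deg"] > out["expected_total"],
        "above",
        np.where(out["n_deg"] < out["expected_total"], "below", "equal"),
    )
    out["direction_of_deviation"] = deviation
    out["stars_total"] = [
        _stars(p, alpha_star, alpha_doublestar) for p in adj_total
    ]
    out["stars_updown"] = [
        _stars(p, alpha_star, alpha_doublestar) for p in adj_updown
    ]
    return ChromosomeEnrichment(out, tuple(warnings), alpha_star, alpha_doublestar)
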