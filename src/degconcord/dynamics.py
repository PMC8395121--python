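"""Three-time-point trajectory classification and adaptation accounting.

Each gene observed at all three time points receives a trajectory label
(c1, c2, c3) over {U, D, N} built from its regulation calls.  The labels are
counted hierarchically: 3 first-level groups (behaviour at t1), 9 second-
level groups (t1, t2) and 27 third-level groups (t1, t2, t3) — the flow
structure behind Sankey/alluvial views of transient regulation.

"Adaptation" of an initially regulated gene means it no longer carries its
initial call at the later time point: it either reverted to N or reversed
direction.  Pure reversion to N is exposed separately (``reverted``) so
that counter-regulation can be distinguished from a plain return to
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import pandas as pd

from .data_model import DOWN, NS, UNOBSERVED, UP, RegulationCalls, shared_universe

__all__ = [
    "TrajectoryFlow",
    "AdaptationSummary",
    "classify_trajectories",
    "adaptation_fraction",
    "persistence_fraction",
    "STATE_OF_CALL",
]

# Regulation calls collapse to single-letter trajectory states.
STATE_OF_CALL = {UP: "U", DOWN: "D", NS: "N"}
STATES = ("U", "D", "N")


@dataclass(frozen=True)
class TrajectoryFlow:
    """Hierarchical trajectory counts over three time points.

    ``labels`` maps each fully observed gene to its (c1, c2, c3) tuple;
    level-k counts aggregate over the first k coordinates.  Genes
    UNOBSERVED at any time point are excluded and tallied in ``n_excluded``.
    """

    labels: pd.Series
    counts_level1: dict
    counts_level2: dict
    counts_level3: dict
    n_excluded: int

    def edge_list(self) -> pd.DataFrame:
        """Sankey-ready edges: parent label -> child label with counts."""
        rows = []
        for (c1, c2), count in sorted(self.counts_level2.items()):
            if count:
                rows.append({"parent": c1, "child": f"{c1},{c2}", "count": count})
        for (c1, c2, c3), count in sorted(self.counts_level3.items()):
            if count:
                rows.append(
                    {"parent": f"{c1},{c2}", "child": f"{c1},{c2},{c3}", "count": count}
                )
        return pd.DataFrame(rows, columns=["parent", "child", "count"])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"t1": c1, "t2": c2, "t3": c3, "count": self.counts_level3[(c1, c2, c3)]}
            for c1, c2, c3 in product(STATES, STATES, STATES)
        ]
        return pd.DataFrame(rows)


def classify_trajectories(
    calls_t1: RegulationCalls,
    calls_t2: RegulationCalls,
    calls_t3: RegulationCalls,
) -> TrajectoryFlow:
    """Label every gene's (t1, t2, t3) behaviour and count hierarchically."""
    universe = shared_universe(calls_t1, calls_t2, calls_t3)
    c1 = calls_t1.reindex(universe).calls
    c2 = calls_t2.reindex(universe).calls
    c3 = calls_t3.reindex(universe).calls
    observed = (c1 != UNOBSERVED) & (c2 != UNOBSERVED) & (c3 != UNOBSERVED)
    n_excluded = int((~observed).sum())

    s1 = c1[observed].map(STATE_OF_CALL)
    s2 = c2[observed].map(STATE_OF_CALL)
    s3 = c3[observed].map(STATE_OF_CALL)
    labels = pd.Series(list(zip(s1, s2, s3)), index=s1.index)

    counts3 = {key: 0 for key in product(STATES, STATES, STATES)}
    for key, n in labels.value_counts().items():
        counts3[key] = int(n)
    counts2 = {key: 0 for key in product(STATES, STATES)}
    counts1 = {s: 0 for s in STATES}
    for (a, b, c), n in counts3.items():
        counts2[(a, b)] += n
        counts1[a] += n
    return TrajectoryFlow(labels, counts1, counts2, counts3, n_excluded)


@dataclass(frozen=True)
class AdaptationSummary:
    """How many initially regulated genes lost their initial call later.

    ``fraction_pct`` is n_adapted / n_initially_altered as a percentage
    truncated to one decimal (116/1058 reports as 10.9, matching how such
    fractions are conventionally printed; None when nothing was initially
    altered); ``reverted_pct`` restricts the numerator to genes that
    returned to NS.
    """

    n_initially_altered: int
    n_adapted: int
    n_reverted: int
    fraction_pct: float | None
    reverted_pct: float | None


def adaptation_fraction(
    calls_initial: RegulationCalls, calls_later: RegulationCalls
) -> AdaptationSummary:
    """Fraction of initially UP/DOWN genes whose later call differs.

    Genes UNOBSERVED at either time point are excluded entirely (the flow
    covers genes measurable at both times).
    """
    universe = shared_universe(calls_initial, calls_later)
    initial = calls_initial.reindex(universe).calls
    later = calls_later.reindex(universe).calls
    observed = (initial != UNOBSERVED) & (later != UNOBSERVED)
    initial, later = initial[observed], later[observed]

    altered = initial.isin([UP, DOWN])
    n_altered = int(altered.sum())
    adapted = altered & (later != initial)
    reverted = altered & (later == NS)
    n_adapted = int(adapted.sum())
    n_reverted = int(reverted.sum())
    if n_altered == 0:
        return AdaptationSummary(0, 0, 0, None, None)

    def pct(numer: int) -> float:
        return int(1000.0 * numer / n_altered) / 10.0

    return AdaptationSummary(
        n_initially_altered=n_altered,
        n_adapted=n_adapted,
        n_reverted=n_reverted,
        fraction_pct=pct(n_adapted),
        reverted_pct=pct(n_reverted),
    )


def persistence_fraction(
    calls_initial: RegulationCalls, calls_later: RegulationCalls
) -> dict:
    """Per direction: fraction of initially-d genes still called d later.

    Returns {UP: fraction or None, DOWN: fraction or None}; None when no
    gene carried the direction initially.  Complements adaptation: for each
    direction, persistence + adapted fraction = 1.
    """
    universe = shared_universe(calls_initial, calls_later)
    initial = calls_initial.reindex(universe).calls
    later = calls_later.reindex(universe).calls
    observed = (initial != UNOBSERVED) & (later != UNOBSERVED)
    initial, later = initial[observed], later[observed]

    out: dict = {}
    for d in (UP, DOWN):
        n_d = int((initial == d).sum())
        out[d] = None if n_d == 0 else int(((initial == d) & (later == d)).sum()) / n_d
    return out
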