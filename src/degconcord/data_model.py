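"""Domain types and I/O for per-gene differential-expression results.

The central container is :class:`DEGTable`: one row per gene with the log2
fold change (treatment over control), raw and FDR-adjusted p-values, and
optional chromosome / biotype annotations plus a per-gene ranking statistic
for enrichment analysis.  A gene whose adjusted p-value is missing is
"unobservable": it exists in the table but is excluded from all significance
counting downstream.

Files are plain TSV with a header row.  Missing values are accepted as
``NA``, ``NaN`` or the empty string on read and always written back as
``NA``, so a write-then-read round trip is the identity on every field
including missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# Regulation call labels.  UP/DOWN require significance and a strict fold
# change sign; NS is observable-but-not-significant; UNOBSERVED marks genes
# with a missing adjusted p-value (or absent from a table entirely).
UP = "UP"
DOWN = "DOWN"
NS = "NS"
UNOBSERVED = "UNOBSERVED"
CALL_LEVELS = (UP, DOWN, NS, UNOBSERVED)

NA_TOKENS = ["NA", "NaN", ""]
NA_WRITE = "NA"

_NUMERIC_COLUMNS = ("log2fc", "pvalue", "adj_pvalue", "rank_stat")
_STRING_COLUMNS = ("chromosome", "biotype")
_ALL_COLUMNS = ("gene_id",) + _NUMERIC_COLUMNS[:1] + _NUMERIC_COLUMNS[1:] + _STRING_COLUMNS
MANDATORY_COLUMNS = ("gene_id", "log2fc")
OPTIONAL_COLUMNS = ("pvalue", "adj_pvalue", "chromosome", "biotype", "rank_stat")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_probability_column(values: pd.Series, name: str) -> None:
    bad = values.dropna()
    bad = bad[(bad < 0.0) | (bad > 1.0)]
    if len(bad):
        gene = bad.index[0]
        raise ValidationError(
            f"column {name!r}: value {bad.iloc[0]!r} for gene {gene!r} "
            "is outside [0, 1]"
        )


@dataclass(frozen=True)
class DEGTable:
    """Per-gene differential-expression results for one platform/time point.

    ``data`` is indexed by gene_id (unique, case-sensitive, whitespace
    trimmed) with columns log2fc, pvalue, adj_pvalue, chromosome, biotype,
    rank_stat.  Missing values are NaN (numeric) or NaN/None (string).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate gene_id {dup!r}")
        for col in _NUMERIC_COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"missing column {col!r}")
        _check_probability_column(df["pvalue"], "pvalue")
        _check_probability_column(df["adj_pvalue"], "adj_pvalue")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        column_map: Mapping[str, str] | None = None,
    ) -> "DEGTable":
        """Build a validated table from a raw DataFrame.

        ``column_map`` maps logical column names (gene_id, log2fc, ...) to
        the physical names present in ``frame``; identity by default.
        """
        cmap = dict(column_map or {})
        physical = {logical: cmap.get(logical, logical) for logical in MANDATORY_COLUMNS + OPTIONAL_COLUMNS}
        missing = [
            f"{logical} (as {phys!r})"
            for logical, phys in physical.items()
            if logical in MANDATORY_COLUMNS and phys not in frame.columns
        ]
        if missing:
            raise ValidationError("missing mandatory columns: " + ", ".join(missing))

        out = pd.DataFrame(index=range(len(frame)))
        gene_id = frame[physical["gene_id"]].astype(str).str.strip()
        for logical in OPTIONAL_COLUMNS + ("log2fc",):
            phys = physical[logical]
            if phys in frame.columns:
                out[logical] = frame[phys].to_numpy()
            else:
                out[logical] = np.nan
        out.index = pd.Index(gene_id, name="gene_id")
        for col in _NUMERIC_COLUMNS:
            out[col] = pd.to_numeric(out[col], errors="raise")
        for col in _STRING_COLUMNS:
            s = out[col]
            if s.dtype == object:
                s = s.astype("string").str.strip()
            out[col] = s.astype("string") if s.notna().any() else pd.Series(
                pd.NA, index=out.index, dtype="string"
            )
        out = out[["log2fc", "pvalue", "adj_pvalue", "chromosome", "biotype", "rank_stat"]]
        return cls(out)

    # -- accessors ---------------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    def __len__(self) -> int:
        return len(self.data)

    @property
    def observable(self) -> pd.Series:
        """Boolean mask: adjusted p-value is present."""
        return self.data["adj_pvalue"].notna()

    @property
    def n_observable(self) -> int:
        return int(self.observable.sum())

    def significant(self, alpha: float = 0.05) -> pd.Series:
        """Boolean mask: adj_pvalue strictly below ``alpha`` (any direction)."""
        return self.data["adj_pvalue"] < alpha

    # -- I/O ---------------------------------------------------------------

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", na_rep=NA_WRITE)


def read_deg_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> DEGTable:
    """Read a tab-separated DE results file into a validated DEGTable.

    Missing values (``NA``/``NaN``/empty) are preserved as missing, never
    coerced to zero.  Duplicate gene ids, probabilities outside [0, 1] and
    absent mandatory columns are hard errors.
    """
    frame = pd.read_csv(
        path,
        sep="\t",
        dtype=str,
        keep_default_na=False,
        na_values=NA_TOKENS,
    )
    return DEGTable.from_frame(frame, column_map)


def write_deg_table(table: DEGTable, path: str | Path) -> None:
    table.write(path)


# ---------------------------------------------------------------------------
# Regulation calls


@dataclass(frozen=True)
class RegulationCalls:
    """Per-gene regulation call in {UP, DOWN, NS, UNOBSERVED}.

    ``calls`` is a Series indexed by gene_id; ``alpha`` records the
    significance cutoff the calls were made at.  Genes absent from the index
    are UNOBSERVED by convention (see :meth:`reindex`).
    """

    calls: pd.Series
    alpha: float = 0.05

    def __post_init__(self) -> None:
        bad = set(self.calls.unique()) - set(CALL_LEVELS)
        if bad:
            raise ValidationError(f"invalid call labels: {sorted(bad)}")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")

    def genes(self, call: str) -> pd.Index:
        return self.calls.index[self.calls == call]

    def counts(self) -> dict[str, int]:
        vc = self.calls.value_counts()
        return {c: int(vc.get(c, 0)) for c in CALL_LEVELS}

    def reindex(self, universe: pd.Index) -> "RegulationCalls":
        """Extend to ``universe``; genes missing from this set become UNOBSERVED."""
        extended = self.calls.reindex(universe, fill_value=UNOBSERVED)
        return RegulationCalls(extended, self.alpha)

    def write(self, path: str | Path) -> None:
        frame = self.calls.rename("call").to_frame()
        frame.index.name = "gene_id"
        frame.to_csv(path, sep="\t")


def read_calls(path: str | Path, alpha: float = 0.05) -> RegulationCalls:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "gene_id" not in frame.columns or "call" not in frame.columns:
        raise ValidationError("call table needs columns gene_id and call")
    s = pd.Series(
        frame["call"].to_numpy(), index=pd.Index(frame["gene_id"].str.strip(), name="gene_id")
    )
    if s.index.has_duplicates:
        dup = s.index[s.index.duplicated()][0]
        raise ValidationError(f"duplicate gene_id {dup!r}")
    return RegulationCalls(s, alpha)


def shared_universe(*call_sets: RegulationCalls) -> pd.Index:
    """Union of gene ids across call sets, in first-seen order."""
    universe: pd.Index | None = None
    for cs in call_sets:
        universe = cs.calls.index if universe is None else universe.union(
            cs.calls.index, sort=False
        )
    if universe is None:
        raise ValueError("at least one call set required")
    return universe


# ---------------------------------------------------------------------------
# Gene sets (GMT)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets: mapping set_name -> frozenset of gene ids."""

    sets: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: set name, description, then >=1 gene ids per line.

    The description is discarded; duplicate genes within one set are
    deduplicated; a duplicated set name is an error.
    """
    sets: dict[str, frozenset] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name = fields[0].strip()
            if name in sets:
                raise ValidationError(f"line {lineno}: duplicate set name {name!r}")
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise ValidationError(f"line {lineno}: set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name, members in collection.items():
            handle.write("\t".join([name, "na"] + sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# Differential exon usage lists


@dataclass(frozen=True)
class DEUList:
    """Gene-level differential-exon-usage adjusted p-values."""

    pvalues: pd.Series

    def __post_init__(self) -> None:
        _check_probability_column(self.pvalues, "deu adj_pvalue")

    def significant(self, cutoff: float = 0.05) -> pd.Index:
        s = self.pvalues
        return s.index[s < cutoff]

    def __len__(self) -> int:
        return len(self.pvalues)


def read_deu_list(path: str | Path) -> DEUList:
    frame = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=NA_TOKENS
    )
    if "gene_id" not in frame.columns or "adj_pvalue" not in frame.columns:
        raise ValidationError("DEU list needs columns gene_id and adj_pvalue")
    idx = pd.Index(frame["gene_id"].str.strip(), name="gene_id")
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise ValidationError(f"duplicate gene_id {dup!r}")
    return DEUList(pd.Series(pd.to_numeric(frame["adj_pvalue"]).to_numpy(), index=idx))
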