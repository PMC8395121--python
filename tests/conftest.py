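"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from degconcord.data_model import DEGTable, RegulationCalls


def make_table(rows: dict) -> DEGTable:
    """Build a DEGTable from {gene_id: (log2fc, adj_pvalue)} or longer tuples.

    Tuple layout: (log2fc, adj_pvalue[, chromosome[, biotype]]); pvalue is
    copied from adj_pvalue; rank_stat left missing.  None means missing.
    """
    records = {}
    for gene, spec in rows.items():
        spec = tuple(spec) + (None,) * (4 - len(spec))
        fc, adj, chrom, biotype = spec
        records[gene] = {
            "log2fc": np.nan if fc is None else fc,
            "pvalue": np.nan if adj is None else adj,
            "adj_pvalue": np.nan if adj is None else adj,
            "chromosome": chrom,
            "biotype": biotype,
            "rank_stat": np.nan,
        }
    frame = pd.DataFrame.from_dict(records, orient="index")
    frame.index.name = "gene_id"
    frame["chromosome"] = frame["chromosome"].astype("string")
    frame["biotype"] = frame["biotype"].astype("string")
    return DEGTable(frame)


def make_calls(mapping: dict, alpha: float = 0.05) -> RegulationCalls:
    """RegulationCalls from {gene_id: 'UP'|'DOWN'|'NS'|'UNOBSERVED'}."""
    s = pd.Series(mapping, dtype=object)
    s.index.name = "gene_id"
    return RegulationCalls(s, alpha)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
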