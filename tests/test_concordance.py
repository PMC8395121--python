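"""Cross-platform comparison operations against hand counts and naive loops."""

import numpy as np
import pandas as pd
import pytest

from degconcord.concordance import (
    classify_regulation,
    consensus_degs,
    deu_overlap,
    directional_overlap,
    inclusion_sweep,
    rank_by_average_fc,
    spearman_concordance,
)
from degconcord.data_model import DOWN, NS, UNOBSERVED, UP, DEUList, RegulationCalls

from conftest import make_calls, make_table


class TestClassifyRegulation:
    @pytest.mark.parametrize(
        "fc,adj,expected",
        [
            (1.2, 0.01, UP),
            (-3.0, 0.2, NS),
            (-0.5, 0.01, DOWN),
            (2.0, None, UNOBSERVED),
            (0.0, 0.01, NS),  # strict sign required
            (1.0, 0.05, NS),  # strict inequality at alpha
        ],
    )
    def test_call_definitions(self, fc, adj, expected):
        table = make_table({"g": (fc, adj)})
        assert classify_regulation(table).calls["g"] == expected

    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            classify_regulation(make_table({"g": (1, 0.1)}), alpha=1.0)


class TestDirectionalOverlap:
    def test_identical_call_sets(self):
        calls = make_calls(
            {f"u{i}": UP for i in range(5)} | {f"d{i}": DOWN for i in range(3)}
        )
        ov = directional_overlap(calls, calls)
        assert (ov.both_up, ov.both_down) == (5, 3)
        assert ov.contradictory_AupBdown == ov.A_only_up == ov.B_only_down == 0

    def test_six_gene_hand_enumeration(self):
        a = make_calls({"g1": UP, "g2": UP, "g3": DOWN, "g4": DOWN, "g5": NS, "g6": UP})
        b = make_calls({"g1": UP, "g2": DOWN, "g3": DOWN, "g4": NS, "g5": UP, "g6": NS})
        ov = directional_overlap(a, b)
        assert ov.both_up == 1 and ov.both_down == 1
        assert ov.contradictory_AupBdown == 1 and ov.contradictory_AdownBup == 0
        assert ov.A_only_up == 1 and ov.A_only_down == 1 and ov.B_only_up == 1

    def test_all_a_ns_leaves_only_b_and_neither(self):
        a = make_calls({"g1": NS, "g2": NS, "g3": NS})
        b = make_calls({"g1": UP, "g2": DOWN, "g3": NS})
        ov = directional_overlap(a, b)
        assert ov.B_only_up == 1 and ov.B_only_down == 1 and ov.neither == 1
        assert ov.both_up == ov.A_only_up == ov.contradictory_AupBdown == 0

    def test_absent_genes_are_unobserved(self):
        a = make_calls({"g1": UP})
        b = make_calls({"g2": DOWN})
        ov = directional_overlap(a, b)
        assert ov.A_only_up == 1 and ov.B_only_down == 1

    def test_detection_fractions_both_senses(self):
        a = make_calls({"g1": UP, "g2": UP, "g3": UP, "g4": DOWN})
        b = make_calls({"g1": UP, "g2": DOWN, "g3": NS, "g4": NS})
        ov = directional_overlap(a, b)
        assert ov.fraction_A_in_B_any[UP] == pytest.approx(2 / 3)
        assert ov.fraction_A_in_B_same[UP] == pytest.approx(1 / 3)
        assert ov.fraction_A_in_B_any[DOWN] == 0.0

    def test_partition_and_naive_loop_oracle(self, rng):
        """Counts match a per-gene loop and partition the union of DEG calls."""
        labels = np.array([UP, DOWN, NS, UNOBSERVED])
        genes = [f"g{i}" for i in range(1000)]
        a = make_calls(dict(zip(genes, rng.choice(labels, 1000, p=[0.2, 0.2, 0.5, 0.1]))))
        b = make_calls(dict(zip(genes, rng.choice(labels, 1000, p=[0.1, 0.3, 0.5, 0.1]))))
        ov = directional_overlap(a, b)
        naive = {k: 0 for k in (
            "both_up", "both_down", "contradictory_AupBdown", "contradictory_AdownBup",
            "A_only_up", "A_only_down", "B_only_up", "B_only_down", "neither")}
        for g in genes:
            ca, cb = a.calls[g], b.calls[g]
            if ca == UP and cb == UP:
                naive["both_up"] += 1
            elif ca == DOWN and cb == DOWN:
                naive["both_down"] += 1
            elif ca == UP and cb == DOWN:
                naive["contradictory_AupBdown"] += 1
            elif ca == DOWN and cb == UP:
                naive["contradictory_AdownBup"] += 1
            elif ca == UP:
                naive["A_only_up"] += 1
            elif ca == DOWN:
                naive["A_only_down"] += 1
            elif cb == UP:
                naive["B_only_up"] += 1
            elif cb == DOWN:
                naive["B_only_down"] += 1
            else:
                naive["neither"] += 1
        for key, value in naive.items():
            assert getattr(ov, key) == value, key
        n_deg_union = sum(
            1 for g in genes if a.calls[g] in (UP, DOWN) or b.calls[g] in (UP, DOWN)
        )
        assert ov.n_either == n_deg_union


class TestInclusionSweep:
    def test_halving_schedule_reaches_printed_endpoint(self):
        table = make_table({"g1": (1, 0.01), "g2": (1, 0.2), "g3": (-1, 0.001)})
        curve = inclusion_sweep(table, table, alpha_fixed=0.05, n_halvings=4)
        assert curve.rows["cutoff_swept"].tolist() == pytest.approx(
            [0.05, 0.025, 0.0125, 0.00625, 0.003125]
        )
        assert round(curve.rows["cutoff_swept"].iloc[-1], 4) == 0.0031

    def test_identical_tables_frequency_one(self):
        table = make_table({f"g{i}": (1, 0.0001 * (i + 1)) for i in range(20)})
        curve = inclusion_sweep(table, table)
        assert (curve.rows["frequency"] == 1.0).all()

    def test_ten_gene_hand_fixture(self):
        adj_a = [0.001, 0.01, 0.02, 0.04, 0.2, 0.004, 0.03, 0.001, 0.5, 0.045]
        adj_b = [0.002, 0.03, 0.004, 0.06, 0.01, 0.02, 0.004, 0.3, 0.04, 0.002]
        table_a = make_table({f"g{i}": (1, a) for i, a in enumerate(adj_a)})
        table_b = make_table({f"g{i}": (1, b) for i, b in enumerate(adj_b)})
        curve = inclusion_sweep(table_a, table_b, 0.05, 2)
        # A-significant at 0.05: all but g4 (0.2), g8 (0.5) -> 8 genes
        # B cutoffs: 0.05 -> {g0,g1,g2,g5,g4?,...}; hand enumeration below
        sig_a = {i for i, a in enumerate(adj_a) if a < 0.05}
        for k, row in curve.rows.iterrows():
            cutoff = 0.05 / 2**k
            sig_b = {i for i, b in enumerate(adj_b) if b < cutoff}
            assert row["n_fixed"] == len(sig_a)
            assert row["n_swept"] == len(sig_b)
            assert row["n_overlap"] == len(sig_a & sig_b)

    def test_monotone_in_halvings(self, rng):
        table_a = make_table({f"g{i}": (1, p) for i, p in enumerate(rng.random(200))})
        table_b = make_table({f"g{i}": (1, p) for i, p in enumerate(rng.random(200))})
        curve = inclusion_sweep(table_a, table_b, n_halvings=6)
        assert (np.diff(curve.rows["n_swept"]) <= 0).all()
        assert (np.diff(curve.rows["n_overlap"]) <= 0).all()


class TestSpearman:
    def test_identical_and_inverted(self):
        fc = {"g1": 1.0, "g2": -2.0, "g3": 0.5, "g4": 3.0}
        table = make_table({g: (v, 0.01) for g, v in fc.items()})
        inverted = make_table({g: (-v, 0.01) for g, v in fc.items()})
        assert spearman_concordance(table, table) == pytest.approx(1.0)
        assert spearman_concordance(table, inverted) == pytest.approx(-1.0)

    def test_five_gene_rank_formula(self):
        fc_a = [1.0, 2.0, 3.0, 4.0, 5.0]
        fc_b = [2.0, 1.0, 4.0, 3.0, 5.0]
        table_a = make_table({f"g{i}": (v, 0.01) for i, v in enumerate(fc_a)})
        table_b = make_table({f"g{i}": (v, 0.01) for i, v in enumerate(fc_b)})
        # rho = 1 - 6 * sum(d^2) / (n(n^2-1)); d = (1,-1,1,-1,0)... wait ranks
        d2 = sum((a - b) ** 2 for a, b in zip([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]))
        expected = 1 - 6 * d2 / (5 * 24)
        assert spearman_concordance(table_a, table_b) == pytest.approx(expected)

    def test_too_few_shared_genes(self):
        table = make_table({"g1": (1, 0.01), "g2": (2, 0.01)})
        with pytest.raises(ValueError, match=">= 3"):
            spearman_concordance(table, table)

    def test_restrict_significant_in_both(self):
        table_a = make_table(
            {"g1": (1, 0.01), "g2": (2, 0.01), "g3": (3, 0.01), "g4": (9, 0.5)}
        )
        table_b = make_table(
            {"g1": (1, 0.01), "g2": (2, 0.01), "g3": (3, 0.01), "g4": (-9, 0.01)}
        )
        rho = spearman_concordance(table_a, table_b, "significant_in_both")
        assert rho == pytest.approx(1.0)  # g4 dropped: not significant in A


class TestConsensus:
    def test_disjoint_significance_empty(self):
        table_a = make_table({"g1": (1, 0.01), "g2": (1, 0.9)})
        table_b = make_table({"g1": (1, 0.9), "g2": (1, 0.01)})
        assert len(consensus_degs(table_a, table_b)) == 0

    def test_opposite_signs_excluded(self):
        table_a = make_table({"g1": (1.0, 0.01)})
        table_b = make_table({"g1": (-1.0, 0.01)})
        assert len(consensus_degs(table_a, table_b)) == 0

    def test_eight_gene_fixture_membership(self):
        table_a = make_table(
            {
                "g1": (1.0, 0.01), "g2": (-2.0, 0.01), "g3": (1.0, 0.2),
                "g4": (0.5, 0.01), "g5": (-1.0, 0.01), "g6": (2.0, 0.01),
                "g7": (0.0, 0.01), "g8": (1.0, None),
            }
        )
        table_b = make_table(
            {
                "g1": (2.0, 0.01), "g2": (-1.0, 0.01), "g3": (1.0, 0.01),
                "g4": (-0.5, 0.01), "g5": (-3.0, 0.2), "g6": (1.0, 0.04),
                "g7": (1.0, 0.01), "g8": (1.0, 0.01),
            }
        )
        consensus = consensus_degs(table_a, table_b)
        assert sorted(consensus.records.index) == ["g1", "g2", "g6"]
        assert consensus.records.loc["g2", "direction"] == DOWN
        assert consensus.records.loc["g1", "avg_log2fc"] == pytest.approx(1.5)

    def test_symmetry_up_to_field_swap(self, rng):
        genes = [f"g{i}" for i in range(300)]
        table_a = make_table(
            {g: (rng.normal(), rng.random()) for g in genes}
        )
        table_b = make_table(
            {g: (rng.normal(), rng.random()) for g in genes}
        )
        ab = consensus_degs(table_a, table_b)
        ba = consensus_degs(table_b, table_a)
        assert list(ab.records.index) == list(ba.records.index)
        assert ab.records["log2fc_A"].tolist() == ba.records["log2fc_B"].tolist()
        assert ab.records["avg_log2fc"].tolist() == pytest.approx(
            ba.records["avg_log2fc"].tolist()
        )


class TestRankByAverageFc:
    def _consensus(self, fcs):
        table_a = make_table({g: (v, 0.01) for g, v in fcs.items()})
        return consensus_degs(table_a, table_a)

    def test_returns_fewer_when_set_smaller(self):
        consensus = self._consensus({"g1": -1.0, "g2": -3.0})
        top = rank_by_average_fc(consensus, DOWN, n=21)
        assert list(top.index) == ["g2", "g1"]

    def test_magnitude_ties_break_lexicographically(self):
        consensus = self._consensus({"gB": -2.0, "gA": -2.0, "gC": -2.0})
        top = rank_by_average_fc(consensus, DOWN, n=2)
        assert list(top.index) == ["gA", "gB"]

    def test_thirty_gene_hand_sort(self, rng):
        fcs = {f"g{i:02d}": -float(rng.integers(1, 100)) / 10 for i in range(30)}
        consensus = self._consensus(fcs)
        top = rank_by_average_fc(consensus, DOWN, n=21)
        expected = sorted(fcs, key=lambda g: (-abs(fcs[g]), g))[:21]
        assert list(top.index) == expected


class TestDeuOverlap:
    def _deu(self, mapping):
        s = pd.Series(mapping, dtype=float)
        s.index.name = "gene_id"
        return DEUList(s)

    def test_identical_lists_full_inclusion(self):
        deu = self._deu({f"g{i}": 0.01 for i in range(10)})
        result = deu_overlap(deu, deu)
        assert result.fraction_of_B_in_A == 1.0

    def test_disjoint_significant_sets(self):
        a = self._deu({"g1": 0.01, "g2": 0.5})
        b = self._deu({"g1": 0.5, "g2": 0.01})
        assert deu_overlap(a, b).n_overlap == 0

    def test_empty_b_fraction_missing(self):
        a = self._deu({"g1": 0.01})
        b = self._deu({"g1": 0.5})
        assert deu_overlap(a, b).fraction_of_B_in_A is None

    def test_printed_inclusion_fraction(self):
        """411 significant on the sequencing side, 321 shared -> 78%."""
        b = self._deu({f"g{i}": 0.01 for i in range(411)})
        a = self._deu(
            {f"g{i}": 0.01 for i in range(321)}
            | {f"g{i}": 0.5 for i in range(321, 411)}
            | {f"x{i}": 0.01 for i in range(5000)}
        )
        result = deu_overlap(a, b)
        assert (result.n_B, result.n_overlap) == (411, 321)
        assert round(100 * result.fraction_of_B_in_A) == 78
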