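import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_deg_table
from prstress.programs import (
    assign_hormone_programs,
    assign_temporal_programs,
    assign_trend_clusters,
    coreg_correlation,
    genotype_trend,
    hormone_program,
    percent,
    program_summary,
    temporal_program,
    trend_cluster,
)


class TestTemporal:
    def test_late_only(self):
        assert temporal_program({1: "ns", 7: "ns", 14: "up", 22: "ns"}) == "late"

    def test_sustained(self):
        assert temporal_program({1: "up", 7: "ns", 14: "up", 22: "up"}) == "sustained"

    def test_all_ns_is_none(self):
        assert temporal_program({1: "ns", 7: "ns", 14: "ns", 22: "ns"}) == "none"

    def test_early_only(self):
        assert temporal_program({1: "ns", 7: "down", 14: "ns", 22: "ns"}) == "early"

    def test_missing_timepoint_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            temporal_program({1: "ns", 7: "ns", 14: "up"})

    def test_assignment_directions(self):
        degs = make_deg_table(
            [
                ("g1", 1, 0.2, 0.9),
                ("g1", 7, 0.1, 0.9),
                ("g1", 14, 2.5, 0.001),
                ("g1", 22, 3.0, 0.001),
                ("g2", 1, -2.0, 0.01),
                ("g2", 7, 0.0, 0.9),
                ("g2", 14, 0.0, 0.9),
                ("g2", 22, 0.0, 0.9),
            ]
        )
        out = assign_temporal_programs(degs).set_index("gene")
        assert out.loc["g1", "temporal_program"] == "late"
        assert out.loc["g1", "direction"] == 1
        assert out.loc["g2", "temporal_program"] == "early"
        assert out.loc["g2", "direction"] == -1


class TestTrendCluster:
    def test_all_positive_is_cluster_1(self):
        assert trend_cluster((1, 1, 1, 1)) == 1

    def test_all_negative_is_cluster_9(self):
        assert trend_cluster((-1, -1, -1, -1)) == 9

    def test_first_up_rest_down_is_cluster_8(self):
        # mirrors the documented semantics of the one-vs-three pattern
        assert trend_cluster((1, -1, -1, -1)) == 8

    def test_sign_flip_adds_eight(self):
        for signs in itertools.product((-1, 1), repeat=4):
            if signs[0] == 1:
                flipped = tuple(-s for s in signs)
                assert trend_cluster(flipped) == trend_cluster(signs) + 8

    def test_all_16_patterns_distinct(self):
        ids = {trend_cluster(s) for s in itertools.product((-1, 1), repeat=4)}
        assert ids == set(range(1, 17))

    def test_invalid_signs_rejected(self):
        with pytest.raises(ValueError):
            trend_cluster((1, 0, 1, 1))

    def test_trend_tie_rules(self):
        assert genotype_trend([1.0, -1.0, 2.0]) == 1
        assert genotype_trend([1.0, -2.0, 1.0]) == 1  # mean 0 -> sign at last point
        assert genotype_trend([-1.0, 2.0, -1.0]) == -1  # mean 0, last negative
        assert genotype_trend([2.0, -4.0, 2.0]) == 1  # mean 0, last positive
        assert genotype_trend([0.0, 0.0, 0.0]) == -1  # exact zero -> negative

    def test_assignment_over_genotypes(self):
        base = [("g1", t, 2.0, 0.001) for t in (1, 7, 14, 22)]
        down = [("g1", t, -2.0, 0.001) for t in (1, 7, 14, 22)]
        tables = {
            "A": make_deg_table(base, condition="A"),
            "B": make_deg_table(base, condition="B"),
            "C": make_deg_table(base, condition="C"),
            "D": make_deg_table(base, condition="D"),
        }
        out = assign_trend_clusters(tables, ["A", "B", "C", "D"])
        assert out.loc[0, "cluster"] == 1
        tables["A"] = make_deg_table(down, condition="A")
        tables["B"] = make_deg_table(down, condition="B")
        tables["C"] = make_deg_table(down, condition="C")
        tables["D"] = make_deg_table(down, condition="D")
        out = assign_trend_clusters(tables, ["A", "B", "C", "D"])
        assert out.loc[0, "cluster"] == 9

    def test_non_deg_gene_receives_no_cluster(self):
        quiet = [("g1", t, 0.1, 0.9) for t in (1, 7, 14, 22)]
        tables = {g: make_deg_table(quiet, condition=g) for g in "ABCD"}
        assert len(assign_trend_clusters(tables, list("ABCD"))) == 0


class TestHormoneProgram:
    def _statuses(self, *pairs):
        return dict(pairs)

    def test_both_up_is_co_regulated(self):
        prog, sa, ja = hormone_program(
            {4: "up"}, {4: "up"}, {4: 2.0}, {4: 3.0}
        )
        assert (prog, sa, ja) == ("co_regulated", 1, 1)

    def test_opposite_directions_is_reciprocal(self):
        prog, sa, ja = hormone_program({4: "up"}, {4: "down"}, {4: 2.0}, {4: -2.0})
        assert prog == "reciprocal"

    def test_single_hormone(self):
        prog, sa, ja = hormone_program(
            {4: "ns", 8: "ns"}, {4: "down"}, {4: 0.1, 8: 0.0}, {4: -2.0}
        )
        assert (prog, sa, ja) == ("ja_only", 0, -1)

    def test_none(self):
        prog, _, _ = hormone_program({4: "ns"}, {4: "ns"}, {4: 0.0}, {4: 0.0})
        assert prog == "none"

    def test_direction_uses_largest_magnitude_deg_point(self):
        prog, sa, _ = hormone_program(
            {2: "up", 8: "down"},
            {2: "up"},
            {2: 1.5, 8: -4.0},
            {2: 2.0},
        )
        assert sa == -1
        assert prog == "reciprocal"

    def test_partition_property(self):
        # the five programs are exhaustive and mutually exclusive over all
        # combinations of per-hormone DEG evidence
        for sa_hit in (0, 1, -1):
            for ja_hit in (0, 1, -1):
                sa_st = {4: {0: "ns", 1: "up", -1: "down"}[sa_hit]}
                ja_st = {4: {0: "ns", 1: "up", -1: "down"}[ja_hit]}
                prog, _, _ = hormone_program(
                    sa_st, ja_st, {4: 2.0 * sa_hit}, {4: 2.0 * ja_hit}
                )
                expected = {
                    (0, 0): "none",
                    (1, 0): "sa_only",
                    (-1, 0): "sa_only",
                    (0, 1): "ja_only",
                    (0, -1): "ja_only",
                    (1, 1): "co_regulated",
                    (-1, -1): "co_regulated",
                    (1, -1): "reciprocal",
                    (-1, 1): "reciprocal",
                }[(sa_hit, ja_hit)]
                assert prog == expected


class TestCoregCorrelation:
    def test_identical_vectors(self):
        v = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        res = coreg_correlation(v, v)
        assert res.r == pytest.approx(1.0)
        assert res.strength == "very strong"

    def test_negated_vectors(self):
        v = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        res = coreg_correlation(v, -v)
        assert res.r == pytest.approx(-1.0)

    def test_fewer_than_three_rejected(self):
        v = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ValueError):
            coreg_correlation(v, v)

    def test_no_outlier_removal(self):
        v = pd.Series([1, 2, 3, 4, 100.0], index=list("abcde"))
        res = coreg_correlation(v, v)
        assert res.outliers == [] and res.n_used == 5


class TestSummary:
    def test_conserved_percentage_from_printed_cluster_sizes(self):
        # 62 all-down + 33 all-up of 167 classified genes -> 57%
        rows = (
            [{"gene": f"d{i}", "cluster": 9} for i in range(62)]
            + [{"gene": f"u{i}", "cluster": 1} for i in range(33)]
            + [{"gene": f"o{i}", "cluster": 2 + i % 7} for i in range(72)]
        )
        trends = pd.DataFrame(rows)
        summary = program_summary(trend_clusters=trends)
        assert summary.n_classified == 167
        assert summary.conserved_pct == 57

    def test_co_expressed_percentage(self):
        assert percent(122, 152) == 80

    def test_hormone_totals(self):
        rows = (
            [{"gene": f"s{i}", "hormone_program": "sa_only"} for i in range(10)]
            + [{"gene": f"j{i}", "hormone_program": "ja_only"} for i in range(42)]
            + [{"gene": f"c{i}", "hormone_program": "co_regulated"} for i in range(49)]
            + [{"gene": f"r{i}", "hormone_program": "reciprocal"} for i in range(2)]
        )
        summary = program_summary(hormone_assignments=pd.DataFrame(rows))
        assert summary.hormone_total() == 103

    def test_empty_assignments_all_zero(self):
        summary = program_summary(
            hormone_assignments=pd.DataFrame(columns=["gene", "hormone_program"])
        )
        assert summary.hormone_total() == 0

    def test_all_genotype_column_and_count_conservation(self, toy_catalog):
        up = [("a1", 14, 2.0, 0.01)]
        tables = {
            g: make_deg_table(up + [("a2", 14, (2.0 if g in "AB" else 0.1), 0.01)], condition=g)
            for g in "ABCD"
        }
        summary = program_summary(catalog=toy_catalog, degs_by_genotype=tables)
        ft = summary.family_table
        # a1 up in all four genotypes; a2 only in A and B
        assert ft.loc["PR-2", "ALL_up"] == 1
        assert summary.all_up_genes == {"a1"}
        # column sums equal per-genotype totals
        for g in "ABCD":
            expected = int((tables[g]["status"] == "up").sum())
            assert ft.loc["total", f"{g}_up"] == expected

    def test_unknown_gene_rejected(self, toy_catalog):
        tables = {g: make_deg_table([("zz", 14, 2.0, 0.01)], condition=g) for g in "ABCD"}
        with pytest.raises(KeyError):
            program_summary(catalog=toy_catalog, degs_by_genotype=tables)

    def test_rounding_half_away_from_zero(self):
        assert percent(1, 8) == 13  # 12.5 -> 13
        assert percent(62, 167) == 37
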