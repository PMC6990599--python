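import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_deg_table
from prstress.cross import (
    StressProfile,
    boxplot_outliers,
    consolidate_profile,
    correlate_stresses,
    evans_label,
    family_attribution,
    round_half_away,
)


def brute_force_quartiles(values):
    """Explicit linear-interpolation (type 7) quartiles."""
    v = sorted(values)
    n = len(v)

    def q(frac):
        h = (n - 1) * frac
        lo = int(math.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    return q(0.25), q(0.75)


def brute_force_correlate(xa, xb, k=2.0):
    """Explicit quartile + covariance-formula oracle for correlate_stresses."""
    flagged = set()
    for vals in (xa, xb):
        q1, q3 = brute_force_quartiles(vals)
        iqr = q3 - q1
        for i, v in enumerate(vals):
            if v < q1 - k * iqr or v > q3 + k * iqr:
                flagged.add(i)
    keep = [i for i in range(len(xa)) if i not in flagged]
    x = [xa[i] for i in keep]
    y = [xb[i] for i in keep]
    mx, my = sum(x) / len(x), sum(y) / len(y)
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy), sorted(flagged)


def profile(stress, mapping):
    return StressProfile(stress, pd.Series(mapping, dtype=float))


class TestConsolidate:
    def test_mean_over_deg_points_only(self):
        degs = make_deg_table(
            [
                ("g1", 1, 0.2, 0.9),
                ("g1", 14, 2.0, 0.01),
                ("g1", 22, 3.0, 0.01),
            ]
        )
        prof = consolidate_profile(degs, "WF")
        assert prof.values["g1"] == pytest.approx(2.5)

    def test_single_deg_point(self):
        degs = make_deg_table([("g1", 14, -2.0, 0.01), ("g1", 22, 0.1, 0.9)])
        prof = consolidate_profile(degs)
        assert prof.values["g1"] == pytest.approx(-2.0)

    def test_never_deg_absent(self):
        degs = make_deg_table([("g1", 14, 0.5, 0.9), ("g2", 14, 2.0, 0.01)])
        prof = consolidate_profile(degs)
        assert "g1" not in prof.genes and "g2" in prof.genes

    def test_value_within_contributing_range(self):
        rng = np.random.default_rng(0)
        rows = []
        for g in range(20):
            for t in (1, 7, 14, 22):
                rows.append((f"g{g}", t, rng.normal(0, 3), rng.random() * 0.1))
        degs = make_deg_table(rows)
        prof = consolidate_profile(degs)
        hits = degs[degs["status"] != "ns"]
        for gene, val in prof.values.items():
            sub = hits.loc[hits["gene"] == gene, "log2fc"]
            assert sub.min() - 1e-9 <= val <= sub.max() + 1e-9


class TestBoxplotOutliers:
    def test_flags_extreme_value(self):
        values = list(range(1, 11)) + [100]
        assert boxplot_outliers(values) == [10]

    def test_constant_sequence_flags_nothing(self):
        assert boxplot_outliers([5.0] * 8) == []

    def test_idempotent_on_survivors(self):
        values = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 100.0]
        flagged = boxplot_outliers(values)
        survivors = [v for i, v in enumerate(values) if i not in flagged]
        assert boxplot_outliers(survivors) == []

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            boxplot_outliers([1, 2, 3])

    def test_matches_brute_force_quartiles(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            vals = rng.normal(0, 1, size=int(rng.integers(4, 60))).tolist()
            got = boxplot_outliers(vals)
            q1, q3 = brute_force_quartiles(vals)
            iqr = q3 - q1
            expected = [
                i
                for i, v in enumerate(vals)
                if v < q1 - 2 * iqr or v > q3 + 2 * iqr
            ]
            assert got == expected


class TestCorrelate:
    def test_skip_gate_below_min_shared(self):
        a = profile("WF", {f"g{i}": i * 1.0 for i in range(4)})
        b = profile("MB", {f"g{i}": i * 2.0 for i in range(4)})
        res = correlate_stresses(a, b)
        assert res.skipped and "fewer than 10" in res.skip_reason
        assert res.r is None

    def test_identical_profiles_very_strong(self):
        vals = {f"g{i}": float(i) for i in range(12)}
        res = correlate_stresses(profile("A", vals), profile("B", vals))
        assert res.r == pytest.approx(1.0)
        assert res.strength == "very strong"
        assert not res.skipped

    def test_correlation_over_intersection_only(self):
        a = {f"g{i}": float(i) for i in range(15)}
        b = {f"g{i}": float(i) for i in range(5, 25)}
        res = correlate_stresses(profile("A", a), profile("B", b))
        assert res.n_shared == 10

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(30)]
        av = dict(zip(genes, rng.normal(size=30)))
        bv = dict(zip(genes, rng.normal(size=30)))
        res1 = correlate_stresses(profile("A", av), profile("B", bv))
        shuffled = list(genes)
        rng.shuffle(shuffled)
        res2 = correlate_stresses(
            profile("A", {g: av[g] for g in shuffled}),
            profile("B", {g: bv[g] for g in shuffled}),
        )
        assert res1.r == pytest.approx(res2.r)
        assert sorted(res1.outliers) == sorted(res2.outliers)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(10, 200))
            genes = [f"g{i}" for i in range(n)]
            xa = rng.normal(0, 1, size=n)
            xb = 0.5 * xa + rng.normal(0, 1, size=n)
            if rng.random() < 0.5:  # sprinkle outliers
                idx = rng.integers(n)
                xa[idx] += 20
            res = correlate_stresses(
                profile("A", dict(zip(genes, xa))), profile("B", dict(zip(genes, xb)))
            )
            # align the oracle to the method's lexicographic shared-gene order
            order = sorted(range(n), key=lambda i: genes[i])
            r_expected, flagged = brute_force_correlate(
                [xa[i] for i in order], [xb[i] for i in order]
            )
            assert res.r == pytest.approx(r_expected, abs=1e-10)
            assert set(res.outliers) == {genes[order[i]] for i in flagged}

    def test_single_pass_removal(self):
        # values engineered so survivors contain a new would-be outlier;
        # a second pass would remove it, the contract forbids that
        vals = [0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 3.0, 50.0]
        genes = [f"g{i}" for i in range(len(vals))]
        a = profile("A", dict(zip(genes, vals)))
        b = profile("B", dict(zip(genes, [v * 1.1 for v in vals])))
        res = correlate_stresses(a, b)
        assert res.n_used == res.n_shared - len(res.outliers)


class TestEvans:
    @pytest.mark.parametrize(
        "r,label",
        [
            (0.94, "very strong"),
            (0.50, "moderate"),
            (-0.72, "strong"),
            (0.0, "very weak"),
            (0.19, "very weak"),
            (0.20, "weak"),
            (-1.0, "very strong"),
        ],
    )
    def test_bands(self, r, label):
        assert evans_label(r) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            evans_label(1.2)


class TestFamilyAttribution:
    def test_half_in_one_family(self, toy_catalog):
        from prstress.io import GeneCatalog, GeneRecord

        cat = GeneCatalog(
            [GeneRecord(f"a{i}", family="PR-2") for i in range(5)]
            + [GeneRecord(f"b{i}", family="PR-5") for i in range(5)]
        )
        prof = profile("WF", {**{f"a{i}": 1.0 for i in range(5)},
                              **{f"b{i}": 1.0 for i in range(5)}})
        table = family_attribution({"WF": prof}, cat)
        assert table.loc["PR-2", "WF"] == 50
        assert table.loc["n_degs", "WF"] == 10

    def test_percents_sum_to_100_within_rounding(self):
        from prstress.io import GeneCatalog, GeneRecord

        rng = np.random.default_rng(3)
        fams = [f"F{i}" for i in range(6)]
        recs, mapping = [], {}
        for i in range(60):
            fam = fams[int(rng.integers(6))]
            recs.append(GeneRecord(f"g{i}", family=fam))
            mapping[f"g{i}"] = float(rng.normal())
        table = family_attribution({"S": profile("S", mapping)}, GeneCatalog(recs))
        total = table.drop(index="n_degs")["S"].sum()
        assert abs(total - 100) <= len(fams) / 2

    def test_unknown_gene_rejected(self, toy_catalog):
        prof = profile("WF", {"nope": 1.0})
        with pytest.raises(KeyError):
            family_attribution({"WF": prof}, toy_catalog)


def test_round_half_away():
    assert round_half_away(0.5) == 1
    assert round_half_away(-0.5) == -1
    assert round_half_away(2.4) == 2
    assert round_half_away(37.125) == 37
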