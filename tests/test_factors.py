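"""Classical factor tests against closed-form textbook values."""

import numpy as np
import pytest

from dietnet import DietMatrix
from dietnet.factors import (
    InsufficientDataError,
    availability_correlation,
    cooccurrence_mass_test,
    group_anova_tukey,
    internest_distance_test,
    mass_breadth_regression,
    niche_breadth_pct,
    paired_shift_test,
    temporal_scores,
    variance_homogeneity,
)

from conftest import make_matrix


class TestAvailabilityCorrelation:
    def test_log_proportional_counts_give_r_one(self):
        avail = {f"t{i}": float(v) for i, v in enumerate([1, 10, 100, 1000])}
        counts = {t: 2 * np.log(a) + 3 for t, a in avail.items()}
        r = availability_correlation(counts, avail)
        assert r.statistic == pytest.approx(1.0)
        assert r.transform == "ln"
        assert r.effect["n"] == 4

    def test_constant_counts_flagged(self):
        avail = {"a": 1.0, "b": 2.0, "c": 3.0}
        r = availability_correlation({"a": 5, "b": 5, "c": 5}, avail)
        assert r.degenerate

    def test_zero_availability_taxa_dropped(self):
        avail = {"a": 1.0, "b": 2.0, "c": 0.0, "d": 4.0}
        r = availability_correlation({"a": 1, "b": 2, "c": 9, "d": 4}, avail)
        assert r.effect["n"] == 3

    def test_too_few_taxa(self):
        with pytest.raises(InsufficientDataError):
            availability_correlation({"a": 1, "b": 2}, {"a": 1.0, "b": 2.0})


class TestMassBreadthRegression:
    def test_exact_linear_relation(self):
        mass = {f"w{i}": float(x) for i, x in enumerate([80, 90, 100, 110])}
        pct = {w: 2 * v for w, v in mass.items()}
        r = mass_breadth_regression(mass, pct)
        assert r.effect["slope"] == pytest.approx(2.0)
        assert r.effect["r2_adj"] == pytest.approx(1.0)

    def test_zero_mass_variance_rejected(self):
        with pytest.raises(InsufficientDataError):
            mass_breadth_regression(
                {"a": 1.0, "b": 1.0, "c": 1.0}, {"a": 1, "b": 2, "c": 3}
            )

    def test_niche_breadth_pct(self):
        m = make_matrix([[1, 1, 0, 0], [1, 1, 1, 1]])
        pct = niche_breadth_pct(m)
        assert pct["w01"] == pytest.approx(50.0)
        assert pct["w02"] == pytest.approx(100.0)


class TestGroupAnova:
    def test_textbook_three_groups(self):
        # hand-computed one-way ANOVA: groups (1,2,3), (4,5,6), (7,8,9)
        # grand mean 5; SSB = 3*(16+0+16) = 54; SSW = 6; F = 27/1 = 27
        values = {f"i{k}": v for k, v in enumerate([1, 2, 3, 4, 5, 6, 7, 8, 9])}
        groups = {f"i{k}": k // 3 + 1 for k in range(9)}
        r = group_anova_tukey(values, groups)
        assert r.statistic == pytest.approx(27.0)
        assert r.df == (2, 6)
        assert "tukey" in r.effect and len(r.effect["tukey"]) == 3

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        values, groups = {}, {}
        for k in range(12):
            g = k % 2
            values[f"i{k}"] = 10.0 * g + rng.normal(0, 1)
            groups[f"i{k}"] = g
        r = group_anova_tukey(values, groups)
        assert r.p_value < 0.001

    def test_all_identical_degenerate(self):
        r = group_anova_tukey(
            {"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0}, {"a": 1, "b": 1, "c": 2, "d": 2}
        )
        assert r.degenerate
        assert r.statistic == 0.0


class TestVarianceHomogeneity:
    def test_scaled_group_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 15)
        b = rng.normal(0, 10, 15)
        r = variance_homogeneity(
            np.concatenate([a, b]), ["x"] * 15 + ["y"] * 15
        )
        assert r.p_value < 0.01

    def test_cv_reported_per_group(self):
        vals = [10.0, 12.0, 8.0, 100.0, 120.0, 80.0]
        r = variance_homogeneity(vals, ["a"] * 3 + ["b"] * 3)
        assert r.effect["cv"]["a"] == pytest.approx(2.0 / 10.0)
        assert r.effect["cv"]["b"] == pytest.approx(20.0 / 100.0)


class TestPairedShift:
    def test_identical_pairs_degenerate(self):
        r = paired_shift_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.degenerate and r.p_value == 1.0

    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=8)
        r = paired_shift_test(x, x + rng.normal(size=8))
        assert r.df == (7,)


class TestCooccurrenceMass:
    def test_missing_mass_lists_taxa(self):
        with pytest.raises(InsufficientDataError, match="tx"):
            cooccurrence_mass_test(
                [("ta", "tb"), ("ta", "tx")], [("tb", "tc")], {"ta": 1, "tb": 2, "tc": 3}
            )

    def test_df_and_no_signal(self):
        rng = np.random.default_rng(3)
        masses = {f"t{i}": float(rng.normal(50, 10)) for i in range(16)}
        taxa = list(masses)
        pairs = [(taxa[i], taxa[j]) for i in range(16) for j in range(i + 1, 16)]
        never, co = pairs[:66], pairs[66:]
        r = cooccurrence_mass_test(never, co, masses)
        assert r.df == (118,)  # 120 pairs split 66/54

    def test_equal_masses_degenerate(self):
        masses = {"a": 5.0, "b": 5.0, "c": 5.0, "d": 5.0}
        r = cooccurrence_mass_test(
            [("a", "b"), ("c", "d")], [("a", "c"), ("b", "d")], masses
        )
        assert r.degenerate


class TestTemporalScores:
    def test_means_and_exclusions(self, caplog):
        with caplog.at_level("WARNING"):
            s = temporal_scores({"a": [1, 17], "b": [9], "c": []})
        assert s["a"] == pytest.approx(9.0)
        assert s["b"] == pytest.approx(9.0)
        assert "c" not in s
        assert any("no scored prey" in r.message for r in caplog.records)


class TestInternestDistance:
    def test_tight_far_clusters_detected(self):
        coords = {}
        labels = {}
        rng = np.random.default_rng(4)
        for i in range(6):
            coords[f"a{i}"] = tuple(rng.normal(0, 1, 2))
            labels[f"a{i}"] = 1
            coords[f"b{i}"] = tuple(rng.normal(500, 1, 2))
            labels[f"b{i}"] = 2
        r = internest_distance_test(coords, labels)
        assert r.p_value < 0.01
        assert r.statistic < 0  # within distances smaller
        assert r.transform == "sqrt"

    def test_df_matches_pair_counts(self):
        rng = np.random.default_rng(5)
        coords = {f"n{i}": tuple(rng.normal(0, 10, 2)) for i in range(12)}
        labels = {f"n{i}": i % 3 + 1 for i in range(12)}
        r = internest_distance_test(coords, labels)
        assert r.df == (64,)  # 66 nest pairs minus 2

    def test_coincident_nests_degenerate(self):
        coords = {c: (0.0, 0.0) for c in "abcd"}
        labels = {"a": 1, "b": 1, "c": 2, "d": 2}
        r = internest_distance_test(coords, labels)
        assert r.degenerate
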