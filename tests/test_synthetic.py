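"""Generator contracts: seeds, limits, planted structure."""

import numpy as np
import pytest

from dietnet import cscore, nodf, to_binary
from dietnet.synthetic import (
    PopulationSpec,
    generate_checkerboard_population,
    generate_clustered_population,
    generate_nested_population,
    generate_null_population,
    generate_population,
    pooled_proportions_for,
)


class TestSpecValidation:
    def test_totals_below_study_filter_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec(totals_range=(2, 10))

    def test_strength_bounds(self):
        with pytest.raises(ValueError):
            PopulationSpec(strength=1.5)

    def test_too_many_clusters(self):
        with pytest.raises(ValueError):
            generate_clustered_population(
                PopulationSpec(n_individuals=4, k_clusters=5, structure="clustered")
            )

    def test_pooled_proportions_shape(self):
        p = pooled_proportions_for(PopulationSpec(n_taxa=16, dominant_share=0.5))
        assert p.sum() == pytest.approx(1.0)
        assert p[0] == pytest.approx(0.5)
        assert (np.diff(p[1:]) <= 0).all()  # geometric tail decays


class TestSeedContract:
    @pytest.mark.parametrize(
        "structure", ["null", "nested", "competitive_refuge", "checkerboard"]
    )
    def test_bit_identical_per_seed(self, structure):
        spec = PopulationSpec(structure=structure, strength=0.7, seed=42)
        a, _ = generate_population(spec)
        b, _ = generate_population(spec)
        assert np.array_equal(a.counts, b.counts)
        assert a.taxon_ids == b.taxon_ids

    def test_different_seeds_differ(self):
        a = generate_null_population(PopulationSpec(seed=1))
        b = generate_null_population(PopulationSpec(seed=2))
        assert not np.array_equal(a.counts, b.counts)


class TestStrengthZeroLimit:
    @pytest.mark.parametrize(
        "structure",
        ["nested", "competitive_refuge", "distinct_preferences", "checkerboard"],
    )
    def test_strength_zero_equals_null_generator(self, structure):
        null = generate_null_population(PopulationSpec(seed=9))
        m, _ = generate_population(
            PopulationSpec(seed=9, structure=structure, strength=0.0)
        )
        assert np.array_equal(null.counts, m.counts)


class TestNullPopulation:
    def test_invariants_at_study_scale(self):
        m = generate_null_population(PopulationSpec(n_individuals=14, n_taxa=16, seed=0))
        assert m.row_totals.min() >= 4
        assert (m.col_totals > 0).all()
        assert m.n_individuals == 14

    def test_column_means_track_pooled(self):
        spec = PopulationSpec(n_individuals=12, n_taxa=6, geometric_ratio=0.6)
        pooled = pooled_proportions_for(spec)
        tot = np.zeros(6)
        n_items = 0
        for s in range(150):
            m = generate_null_population(
                PopulationSpec(n_individuals=12, n_taxa=6, geometric_ratio=0.6, seed=s)
            )
            tot += m.col_totals
            n_items += m.counts.sum()
        assert np.allclose(tot / n_items, pooled, atol=0.01)


class TestNestedPopulation:
    def test_noiseless_limit_is_perfectly_stepped(self):
        m, masses = generate_nested_population(
            PopulationSpec(structure="nested", strength=1.0, seed=1)
        )
        b = (m.counts > 0).astype(int)
        # every row's support is a prefix of the taxon ranking -> rows are
        # nested subsets ordered by breadth (rows with equal breadth are
        # identical, so they tie rather than break the stepping)
        for row in b:
            support = np.flatnonzero(row)
            assert support.max() == len(support) - 1  # contiguous prefix
        assert nodf(to_binary(m)).col_nodf == pytest.approx(100.0)

    def test_noiseless_nestedness_is_significant(self):
        from dietnet import nodf_test

        m, _ = generate_nested_population(
            PopulationSpec(structure="nested", strength=1.0, n_individuals=12, seed=11)
        )
        r = nodf_test(to_binary(m), n_null=300, seed=12)
        assert r.verdict == "nested"

    def test_mass_breadth_relation_recovered(self):
        from dietnet.factors import mass_breadth_regression, niche_breadth_pct

        m, masses = generate_nested_population(
            PopulationSpec(structure="nested", strength=1.0, n_individuals=14, seed=2)
        )
        r = mass_breadth_regression(masses.to_dict(), niche_breadth_pct(m).to_dict())
        assert r.effect["slope"] > 0
        assert r.p_value < 0.05


class TestClusteredPopulation:
    def test_labels_partition_individuals(self):
        m, labels = generate_clustered_population(
            PopulationSpec(structure="competitive_refuge", k_clusters=3, seed=3)
        )
        assert set(labels) >= set(m.individual_ids)
        assert set(labels.values()) == {1, 2, 3}

    def test_refuge_clusters_share_dominant(self):
        m, labels = generate_clustered_population(
            PopulationSpec(
                structure="competitive_refuge", strength=1.0, n_individuals=9,
                k_clusters=3, seed=4,
            )
        )
        dominant = m.taxon_ids[0]
        j = m.taxon_ids.index(dominant)
        assert (m.counts[:, j] > 0).all()

    def test_distinct_clusters_have_disjoint_supports(self):
        m, labels = generate_clustered_population(
            PopulationSpec(
                structure="distinct_preferences", strength=1.0, n_individuals=9,
                k_clusters=3, seed=5,
            )
        )
        supports = {}
        for i, ind in enumerate(m.individual_ids):
            supports.setdefault(labels[ind], set()).update(
                np.flatnonzero(m.counts[i] > 0)
            )
        for a in supports:
            for b in supports:
                if a != b:
                    assert not (supports[a] & supports[b])


class TestCheckerboardPopulation:
    def test_two_by_two_limit(self):
        m = generate_checkerboard_population(
            PopulationSpec(n_individuals=2, n_taxa=2, structure="checkerboard",
                           strength=1.0, seed=6)
        )
        b = (m.counts > 0).astype(int)
        assert b.tolist() in ([[1, 0], [0, 1]], [[0, 1], [1, 0]])

    def test_segregated_pairs_never_cooccur_at_any_strength(self):
        for strength in (0.4, 0.7, 1.0):
            spec = PopulationSpec(structure="checkerboard", strength=strength, seed=7)
            m = generate_checkerboard_population(spec)
            alternatives = list(range(1, spec.n_taxa))
            n_seg = int(round(strength * len(alternatives)))
            g0, g1 = alternatives[:n_seg][0::2], alternatives[:n_seg][1::2]
            name = {t: i for i, t in enumerate(m.taxon_ids)}
            present = set(m.taxon_ids)
            b = (m.counts > 0).astype(int)
            for a in g0:
                for c in g1:
                    ta, tc = f"taxon{a+1:02d}", f"taxon{c+1:02d}"
                    if ta in present and tc in present:
                        assert (b[:, name[ta]] * b[:, name[tc]]).sum() == 0

    def test_cscore_monotone_at_three_strengths(self):
        means = []
        for strength in (0.0, 0.5, 1.0):
            cs = [
                cscore(to_binary(generate_checkerboard_population(
                    PopulationSpec(structure="checkerboard", strength=strength, seed=s)
                )))
                for s in range(60)
            ]
            means.append(np.mean(cs))
        assert means[0] <= means[1] <= means[2]
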