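import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from layersim.founders import LociPartition
from layersim.traits import (
    GENETIC_CORRELATIONS,
    HERITABILITIES,
    INDEX_WEIGHTS,
    TraitArchitecture,
    TraitValues,
    base_genetic_covariance,
    genic_variance,
    sample_effects,
    simulate_phenotypes,
    true_genetic_values,
)


def _part(n_qtl, n_sites=50):
    idx = np.arange(n_sites)
    return LociPartition(qtl_idx=(idx[:n_qtl],), snp_idx=(idx[n_qtl : n_qtl + 5],), neutral_idx=(idx[n_qtl + 5 : n_qtl + 10],))


class TestBaseCovariance:
    def test_matches_stated_parameters(self):
        c = base_genetic_covariance()
        np.testing.assert_allclose(np.diag(c), [0.18, 0.22, 0.25])
        sd = np.sqrt(np.diag(c))
        assert c[0, 1] / (sd[0] * sd[1]) == pytest.approx(0.75)
        assert c[1, 2] / (sd[1] * sd[2]) == pytest.approx(0.70)
        assert c[0, 2] / (sd[0] * sd[2]) == pytest.approx(0.60)

    def test_positive_definite(self):
        assert np.all(np.linalg.eigvalsh(base_genetic_covariance()) > 0)

    def test_index_weights_sum_to_one(self):
        assert INDEX_WEIGHTS.sum() == pytest.approx(1.0)


class TestSampleEffects:
    def test_founder_genic_covariance_matches_target(self, tiny_pop, tiny_partition):
        freqs = tiny_pop.allele_frequencies(tiny_partition.qtl_idx)
        target = base_genetic_covariance()
        arch = sample_effects(tiny_partition, freqs, target, seed=5)
        w = 2 * freqs * (1 - freqs)
        realized = (arch.effects * w[:, None]).T @ arch.effects
        np.testing.assert_allclose(realized, target, atol=1e-10)

    def test_zero_target_gives_zero_effects(self, tiny_pop, tiny_partition):
        freqs = tiny_pop.allele_frequencies(tiny_partition.qtl_idx)
        arch = sample_effects(tiny_partition, freqs, np.zeros((3, 3)), seed=5)
        assert np.all(arch.effects == 0)
        tv = true_genetic_values(tiny_pop, arch)
        assert np.all(tv.tbv == 0)

    def test_monomorphic_qtl_rejected(self, tiny_partition):
        freqs = np.full(10, 0.3)
        freqs[3] = 0.0
        with pytest.raises(ValueError, match="monomorphic"):
            sample_effects(tiny_partition, freqs, base_genetic_covariance(), seed=1)

    def test_two_qtl_unit_effects_hand_formula(self):
        # 2 QTL, stated frequencies, unit effects: per-trait genic variance
        # equals the enumerated 2 sum p(1-p) a a'
        p = np.array([0.2, 0.5])
        eff = np.ones((2, 3))
        hand = sum(2 * p[j] * (1 - p[j]) * np.outer(eff[j], eff[j]) for j in range(2))
        np.testing.assert_allclose(genic_variance(p, eff), np.diag(hand))

    def test_deterministic(self, tiny_pop, tiny_partition):
        freqs = tiny_pop.allele_frequencies(tiny_partition.qtl_idx)
        a1 = sample_effects(tiny_partition, freqs, base_genetic_covariance(), seed=5)
        a2 = sample_effects(tiny_partition, freqs, base_genetic_covariance(), seed=5)
        np.testing.assert_array_equal(a1.effects, a2.effects)

    def test_residual_cov_diagonal_enforced(self):
        with pytest.raises(ValueError, match="diagonal"):
            TraitArchitecture(
                effects=np.zeros((2, 3)),
                base_genetic_cov=np.eye(3),
                residual_cov=np.full((3, 3), 0.1),
            )


class TestTrueGeneticValues:
    def test_homozygous_reference_gives_zero(self, tiny_partition):
        n_loci = 50
        haps = [np.zeros((4, n_loci), np.uint8)]
        from layersim.founders import HaplotypePopulation

        pop = HaplotypePopulation(haplotypes=haps, animal_ids=[1, 2])
        arch = TraitArchitecture(
            effects=np.ones((10, 3)), base_genetic_cov=np.eye(3), residual_cov=np.eye(3), partition=_part(10, 50)
        )
        assert np.all(true_genetic_values(pop, arch).tbv == 0)

    def test_single_het_qtl_unit_effect(self):
        from layersim.founders import HaplotypePopulation

        haps = [np.zeros((2, 50), np.uint8)]
        haps[0][0, 0] = 1  # heterozygous at the first locus (the QTL)
        pop = HaplotypePopulation(haplotypes=haps, animal_ids=[1])
        arch = TraitArchitecture(
            effects=np.ones((1, 3)), base_genetic_cov=np.eye(3), residual_cov=np.eye(3), partition=_part(1, 50)
        )
        np.testing.assert_allclose(true_genetic_values(pop, arch).tbv, [[1.0, 1.0, 1.0]])

    def test_equals_bruteforce_loop(self, tiny_pop, tiny_partition):
        freqs = tiny_pop.allele_frequencies(tiny_partition.qtl_idx)
        arch = sample_effects(tiny_partition, freqs, base_genetic_covariance(), seed=2)
        sub = tiny_pop.subset(np.arange(5))
        tv = true_genetic_values(sub, arch)
        qtl = tiny_partition.qtl_idx[0]
        for i in range(5):
            for t in range(3):
                expected = 0.0
                for j, locus in enumerate(qtl):
                    dose = int(sub.haplotypes[0][2 * i, locus]) + int(sub.haplotypes[0][2 * i + 1, locus])
                    expected += dose * arch.effects[j, t]
                assert tv.tbv[i, t] == pytest.approx(expected)


class TestSimulatePhenotypes:
    def test_zero_residual_equals_tbv(self):
        arch = TraitArchitecture(
            effects=np.zeros((1, 3)), base_genetic_cov=np.eye(3), residual_cov=np.zeros((3, 3))
        )
        tv = TraitValues(tbv=np.arange(12.0).reshape(4, 3))
        out = simulate_phenotypes(tv, arch, np.zeros((4, 3)), seed=1)
        np.testing.assert_array_equal(out.phenotypes, tv.tbv)

    def test_residual_variance_monte_carlo(self):
        n = 10000
        rv = np.array([0.82, 0.78, 0.75])
        arch = TraitArchitecture(
            effects=np.zeros((1, 3)), base_genetic_cov=np.eye(3), residual_cov=np.diag(rv)
        )
        tv = TraitValues(tbv=np.zeros((n, 3)))
        out = simulate_phenotypes(tv, arch, np.zeros((n, 3)), seed=4)
        emp = (out.phenotypes - tv.tbv).var(axis=0, ddof=1)
        se = rv * np.sqrt(2.0 / (n - 1))
        assert np.all(np.abs(emp - rv) < 3 * se)

    def test_availability_schedule_passed_through(self):
        arch = TraitArchitecture(
            effects=np.zeros((1, 3)), base_genetic_cov=np.eye(3), residual_cov=np.eye(3)
        )
        sched = np.array([[0.5, 1.0, np.inf]])
        out = simulate_phenotypes(TraitValues(tbv=np.zeros((1, 3))), arch, sched, seed=0)
        np.testing.assert_array_equal(out.available_from, sched)


class TestGenicVariance:
    def test_single_qtl_half(self):
        assert genic_variance([0.5], np.array([[1.0]])) == pytest.approx(0.5)

    def test_fixed_qtl_contributes_zero(self):
        assert genic_variance([0.0, 1.0], np.array([[2.0], [3.0]]))[0] == 0.0

    def test_index_weighting(self):
        p = np.array([0.5])
        eff = np.array([[1.0, 2.0, 0.0]])
        w = np.array([0.2, 0.35, 0.45])
        combined = 1.0 * 0.2 + 2.0 * 0.35
        assert genic_variance(p, eff, index_weights=w) == pytest.approx(0.5 * combined**2)

    def test_matches_hwe_enumeration_three_qtl(self):
        # exhaustive 27-genotype enumeration at linkage equilibrium
        p = np.array([0.1, 0.4, 0.7])
        eff = np.array([[0.3], [-0.5], [0.8]])
        var_formula = genic_variance(p, eff)[0]
        probs = {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p**2}
        mean = 0.0
        mean2 = 0.0
        for g in itertools.product([0, 1, 2], repeat=3):
            pr = np.prod([probs[g[j]][j] for j in range(3)])
            val = sum(g[j] * eff[j, 0] for j in range(3))
            mean += pr * val
            mean2 += pr * val**2
        assert var_formula == pytest.approx(mean2 - mean**2)

    @given(
        p=st.floats(0.01, 0.99),
        a=st.floats(-3, 3),
    )
    @settings(max_examples=50, deadline=None)
    def test_allele_label_swap_invariance(self, p, a):
        v1 = genic_variance([p], np.array([[a]]))[0]
        v2 = genic_variance([1 - p], np.array([[-a]]))[0]
        assert v1 == pytest.approx(v2)

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            genic_variance([1.2], np.array([[1.0]]))


def test_trait_values_frame_roundtrip():
    from layersim.traits import TraitValues, trait_values_frame

    tv = TraitValues(
        tbv=np.arange(6.0).reshape(2, 3),
        phenotypes=np.arange(6.0).reshape(2, 3) + 0.5,
        available_from=np.full((2, 3), 1.5),
    )
    df = trait_values_frame(tv, [7, 8], [0.0, 0.0], ["F", "M"])
    assert len(df) == 2 * 3 * 2
    got = df[(df.animal_id == 7) & (df.trait == 2) & df.is_tbv]["value"].iloc[0]
    assert got == 1.0
    phen = df[(df.animal_id == 8) & (df.trait == 3) & ~df.is_tbv]
    assert phen["value"].iloc[0] == 5.5 and phen["available_from"].iloc[0] == 1.5
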