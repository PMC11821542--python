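import numpy as np
import pytest
from scipy import stats

from anchorpgs import synthetic_admix as sim


class TestAncestralFrequencies:
    def test_zero_fst_is_no_drift_identity(self):
        f = sim.draw_ancestral_frequencies(50, 0.0, seed=3)
        np.testing.assert_array_equal(f.f_eu, f.f_af)

    def test_frequencies_within_clipping_bounds(self):
        f = sim.draw_ancestral_frequencies(5000, 0.45, seed=3)
        assert f.f_eu.min() >= 0.01 and f.f_eu.max() <= 0.99
        assert f.f_af.min() >= 0.01 and f.f_af.max() <= 0.99

    def test_hudson_fst_matches_target(self):
        # oracle: Hudson estimator computed on the simulated frequency pairs
        f = sim.draw_ancestral_frequencies(100_000, 0.15, seed=11)
        assert abs(sim.hudson_fst(f.f_eu, f.f_af) - 0.15) < 0.02

    def test_invalid_fst_raises(self):
        with pytest.raises(ValueError, match="fst"):
            sim.draw_ancestral_frequencies(10, 1.0, seed=0)
        with pytest.raises(ValueError, match="fst"):
            sim.draw_ancestral_frequencies(10, -0.1, seed=0)


class TestTracts:
    def test_mean_tract_length_matches_poisson_rate(self, rng):
        # empirical mean of inter-switch distances vs 1/g Morgans = 10 cM
        lengths = []
        for _ in range(400):
            bounds, _ = sim.simulate_tracts(rng, 1000.0, 10.0, 0.5)
            gaps = np.diff(np.concatenate(([0.0], bounds)))[:-1]  # drop censored tract
            lengths.append(gaps)
        lengths = np.concatenate(lengths)
        assert abs(lengths.mean() - 10.0) / 10.0 < 0.05

    def test_tract_lengths_exponential_ks(self, rng):
        lengths = []
        for _ in range(200):
            bounds, _ = sim.simulate_tracts(rng, 2000.0, 10.0, 0.5)
            lengths.append(np.diff(np.concatenate(([0.0], bounds)))[:-1])
        lengths = np.concatenate(lengths)
        pval = stats.kstest(lengths, "expon", args=(0, 10.0)).pvalue
        assert pval > 0.01

    def test_theta_zero_gives_all_european(self):
        cfg = sim.SimulationConfig(
            n_individuals=10, n_variants=30, n_causal=0, seed=5,
            theta_distribution=("fixed", 0.0),
        )
        freqs = sim.draw_ancestral_frequencies(30, 0.15, seed=5)
        cohort = sim.simulate_admixed_genomes(cfg, freqs)
        assert np.all(cohort.hap_ancestry == 1.0)

    def test_genotype_is_haplotype_sum(self, tiny_cohort):
        _, _, cohort = tiny_cohort
        np.testing.assert_array_equal(
            cohort.genotypes, cohort.haplotypes[:, 0] + cohort.haplotypes[:, 1]
        )

    def test_fixed_seed_bit_identical(self):
        cfg = sim.SimulationConfig(n_individuals=8, n_variants=25, n_causal=5, seed=77)
        freqs = sim.draw_ancestral_frequencies(25, 0.15, seed=77)
        a = sim.simulate_admixed_genomes(cfg, freqs)
        b = sim.simulate_admixed_genomes(cfg, freqs)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
        np.testing.assert_array_equal(a.hap_ancestry, b.hap_ancestry)
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_ancestry_error_rate_blurs_posteriors(self):
        cfg = sim.SimulationConfig(
            n_individuals=5, n_variants=20, n_causal=0, seed=5,
            ancestry_error_rate=0.1,
        )
        freqs = sim.draw_ancestral_frequencies(20, 0.15, seed=5)
        cohort = sim.simulate_admixed_genomes(cfg, freqs)
        assert set(np.unique(cohort.hap_ancestry)) <= {0.1, 0.9}


class TestCausalSelection:
    def test_uniform_distinct_indices(self):
        cfg = sim.SimulationConfig(n_individuals=2, n_variants=10_000, n_causal=100,
                                   seed=1)
        table = sim.default_variant_table(10_000, 100_000_000,
                                          np.random.default_rng(1))
        causal = sim.select_causal_variants(cfg, table)
        assert len(causal) == 100
        assert np.unique(causal.indices).shape[0] == 100
        assert causal.indices.max() < 10_000

    def test_zero_causal_empty(self):
        cfg = sim.SimulationConfig(n_individuals=2, n_variants=100, n_causal=0, seed=1)
        table = sim.default_variant_table(100, 1_000_000, np.random.default_rng(1))
        assert len(sim.select_causal_variants(cfg, table)) == 0

    def test_clustered_half_inside_regions(self):
        # dense map so 10-kb windows hold ~50 variants each
        cfg = sim.SimulationConfig(
            n_individuals=2, n_variants=10_000, n_causal=1_000, seed=2,
            placement="clustered", chrom_length_bp=2_000_000,
        )
        table = sim.default_variant_table(10_000, 2_000_000, np.random.default_rng(2))
        causal = sim.select_causal_variants(cfg, table)
        assert len(causal) == 1_000
        assert len(causal.regions) == 100
        pos = table["pos"].to_numpy()[causal.indices]
        inside = np.zeros(pos.shape[0], dtype=bool)
        for s, e in causal.regions:
            inside |= (pos >= s) & (pos < e)
        assert inside.sum() == 500

    def test_clustered_insufficient_windows_raises(self):
        cfg = sim.SimulationConfig(
            n_individuals=2, n_variants=100, n_causal=100, seed=2,
            placement="clustered", chrom_length_bp=30_000,
        )
        table = sim.default_variant_table(100, 30_000, np.random.default_rng(2))
        with pytest.raises(ValueError, match="regions"):
            sim.select_causal_variants(cfg, table)


class TestEffectSizes:
    def test_rho_one_identity(self):
        f = sim.draw_ancestral_frequencies(100, 0.15, seed=4)
        eff = sim.draw_effect_sizes(np.arange(100), f, rho=1.0, seed=4)
        np.testing.assert_array_equal(eff.gamma_eu, eff.gamma_af)

    def test_frequency_scale_at_half(self):
        # [2 * 0.5 * 0.5]^(-0.25) = 2^(1/4)
        f = sim.AncestralFrequencies(f_eu=np.array([0.5]), f_af=np.array([0.5]))
        draws = [
            sim.draw_effect_sizes(
                np.array([0]), f, effect_dist="frequency_scaled", rho=1.0, seed=s
            ).gamma_eu[0]
            for s in range(4000)
        ]
        assert abs(np.std(draws) - 2 ** 0.25) < 0.05
        assert abs(2 ** 0.25 - 1.189207) < 1e-6

    def test_correlation_recovered(self):
        f = sim.draw_ancestral_frequencies(100_000, 0.15, seed=6)
        eff = sim.draw_effect_sizes(np.arange(100_000), f, rho=0.7, seed=6)
        r = np.corrcoef(eff.gamma_eu, eff.gamma_af)[0, 1]
        assert abs(r - 0.7) < 0.01

    @pytest.mark.parametrize("rho", [-0.5, 0.0, 0.9])
    def test_marginal_variance_ratio_one(self, rho):
        f = sim.draw_ancestral_frequencies(100_000, 0.15, seed=7)
        eff = sim.draw_effect_sizes(
            np.arange(100_000), f, effect_dist="frequency_scaled", rho=rho, seed=7
        )
        assert abs(np.var(eff.gamma_af) / np.var(eff.gamma_eu) - 1.0) < 0.02

    def test_degenerate_frequency_raises(self):
        f = sim.AncestralFrequencies(f_eu=np.array([0.0]), f_af=np.array([0.5]))
        with pytest.raises(ValueError, match="scaling"):
            sim.draw_effect_sizes(
                np.array([0]), f, effect_dist="frequency_scaled", seed=0
            )

    def test_invalid_rho_raises(self):
        f = sim.draw_ancestral_frequencies(5, 0.1, seed=1)
        with pytest.raises(ValueError, match="rho"):
            sim.draw_effect_sizes(np.arange(5), f, rho=1.5, seed=0)


class TestPhenotype:
    def test_noiseless_limit(self, tiny_cohort):
        _, freqs, cohort = tiny_cohort
        eff = sim.draw_effect_sizes(np.arange(10), freqs, seed=8)
        phe = sim.simulate_phenotype(cohort, eff, h2=1.0, seed=8)
        np.testing.assert_array_equal(phe.values, phe.genetic_values)
        assert phe.noise_sd == 0.0

    def test_zero_effects_raise(self, tiny_cohort):
        _, _, cohort = tiny_cohort
        eff = sim.EffectSizes(
            indices=np.arange(10), gamma_eu=np.zeros(10), gamma_af=np.zeros(10)
        )
        with pytest.raises(ValueError, match="variance"):
            sim.simulate_phenotype(cohort, eff, h2=0.5, seed=0)

    def test_realized_heritability(self):
        cfg = sim.SimulationConfig(
            n_individuals=4000, n_variants=200, n_causal=100, seed=21,
            theta_distribution=("uniform", 0.0, 1.0),
        )
        freqs = sim.draw_ancestral_frequencies(200, 0.15, seed=21)
        cohort = sim.simulate_admixed_genomes(cfg, freqs)
        eff = sim.draw_effect_sizes(np.arange(100), freqs, seed=21)
        phe = sim.simulate_phenotype(cohort, eff, h2=0.6, seed=21)
        assert abs(phe.realized_h2 - 0.6) < 0.05

    def test_tract_mode_uses_both_effect_tracks(self, tiny_cohort):
        _, freqs, cohort = tiny_cohort
        eff = sim.draw_effect_sizes(np.arange(10), freqs, rho=0.0, seed=9)
        tract = sim.simulate_phenotype(
            cohort, eff, h2=1.0, ancestry_specific=True, effect_mode="tract"
        )
        group = sim.simulate_phenotype(
            cohort, eff, h2=1.0, ancestry_specific=True, effect_mode="group"
        )
        shared = sim.simulate_phenotype(cohort, eff, h2=1.0)
        assert not np.allclose(tract.values, shared.values)
        assert not np.allclose(tract.values, group.values)
        # tract mode reduces to the shared model when both tracks agree
        eff_same = sim.EffectSizes(
            indices=eff.indices, gamma_eu=eff.gamma_eu, gamma_af=eff.gamma_eu
        )
        t2 = sim.simulate_phenotype(
            cohort, eff_same, h2=1.0, ancestry_specific=True, effect_mode="tract"
        )
        s2 = sim.simulate_phenotype(cohort, eff_same, h2=1.0)
        np.testing.assert_allclose(t2.values, s2.values)


class TestScenarioGrid:
    def test_exactly_24_scenarios(self):
        grid = sim.scenario_grid()
        assert len(grid) == 24
        combos = {
            (c.n_causal, c.placement, c.effect_dist, c.h2) for c in grid
        }
        assert len(combos) == 24

    def test_config_invariants(self):
        with pytest.raises(ValueError, match="h2"):
            sim.SimulationConfig(n_individuals=1, n_variants=10, n_causal=1, seed=0,
                                 h2=0.0)
        with pytest.raises(ValueError, match="n_causal"):
            sim.SimulationConfig(n_individuals=1, n_variants=10, n_causal=11, seed=0)
        with pytest.raises(ValueError, match="nondecreasing"):
            sim.SimulationConfig(
                n_individuals=1, n_variants=3, n_causal=1, seed=0,
                genetic_map=np.array([1.0, 0.5, 2.0]),
            )
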