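import numpy as np
import pandas as pd
import pytest

from anchorpgs.anchor_core import (
    DecomposedPGS,
    assign_bins,
    bin_and_fit,
    bootstrap_fit,
    decompose_pgs,
    estimate_rho,
    fit_anchor,
    pool_traits,
    residualize,
)
from anchorpgs.pgs_engine import PgsWeights, ReferenceSlope


def _scores(rng, n=300, theta=None):
    theta = rng.uniform(0.1, 0.9, n) if theta is None else theta
    return DecomposedPGS(
        epgs=rng.normal(size=n), apgs=rng.normal(size=n), theta=theta
    )


class TestResidualize:
    def test_orthogonal_mean_zero_unchanged(self, rng):
        c = rng.normal(size=50)
        x = rng.normal(size=50)
        Q, _ = np.linalg.qr(np.column_stack([np.ones(50), c]))
        x -= Q @ (Q.T @ x)  # orthogonal to span{1, c}, hence mean-zero
        x_res = residualize(x, c)
        np.testing.assert_allclose(x_res, x, atol=1e-10)

    def test_residual_orthogonal_to_covariates(self, rng):
        C = rng.normal(size=(80, 3))
        x = rng.normal(size=80)
        r = residualize(x, C)
        assert abs(r.mean()) < 1e-8
        for j in range(3):
            assert abs(r @ C[:, j]) < 1e-8

    def test_matches_projection_matrix_oracle(self, rng):
        C = rng.normal(size=(40, 2))
        x = rng.normal(size=40)
        X = np.column_stack([np.ones(40), C])
        P = X @ np.linalg.inv(X.T @ X) @ X.T
        np.testing.assert_allclose(residualize(x, C), x - P @ x, atol=1e-10)

    def test_collinear_covariates_raise(self, rng):
        c = rng.normal(size=30)
        C = np.column_stack([c, 2 * c])
        with pytest.raises(ValueError, match="collinear"):
            residualize(rng.normal(size=30), C)


class TestFitAnchor:
    def test_exact_linear_recovery(self, rng):
        s = _scores(rng)
        Y = 3.0 + 2.0 * s.epgs + 1.0 * s.apgs
        fit = fit_anchor(Y, s, "fixed_zero")
        # scores are mean-centered internally, so the intercept absorbs means
        assert fit.beta_eu == pytest.approx(2.0)
        assert fit.beta_af == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(
            3.0 + 2.0 * s.epgs.mean() + s.apgs.mean()
        )

    def test_free_mode_recovers_interaction(self, rng):
        s = _scores(rng, n=500)
        e = s.epgs - s.epgs.mean()
        a = s.apgs - s.apgs.mean()
        Y = (2.0 * e + 1.0 * a) * (1.0 + 0.5 * s.theta)
        fit = fit_anchor(Y, s, "free")
        assert fit.beta_eu == pytest.approx(2.0, abs=0.02)
        assert fit.beta_af == pytest.approx(1.0, abs=0.02)
        assert fit.omega == pytest.approx(0.5, abs=0.02)

    def test_grid_matches_finer_grid_oracle(self, rng):
        s = _scores(rng, n=200)
        Y = (1.5 * s.epgs + 0.5 * s.apgs) * (1 + 0.3 * s.theta) + rng.normal(size=200)
        fit = fit_anchor(Y, s, "free")
        # brute-force 10x finer grid, independent implementation
        e = residualize(s.epgs)
        a = residualize(s.apgs)
        best = np.inf
        for r in np.linspace(0, 1, 10_000):
            z = r * e + (1 - r) * a
            X = np.column_stack([np.ones(200), z, z * s.theta])
            coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
            sse = float(((Y - X @ coef) ** 2).sum())
            best = min(best, sse)
        # within one coarse-grid step of the finer optimum
        sse_step = np.abs(fit.sse - best)
        assert fit.sse >= best - 1e-9
        assert sse_step / best < 1e-3

    def test_constant_phenotype_raises(self, rng):
        with pytest.raises(ValueError, match="constant"):
            fit_anchor(np.ones(100), _scores(rng, n=100))

    def test_too_few_individuals_raises(self, rng):
        with pytest.raises(ValueError, match="10"):
            fit_anchor(np.arange(5.0), _scores(rng, n=5))

    def test_scale_equivariance(self, rng):
        s = _scores(rng, n=400)
        Y = 1.0 + 0.8 * s.epgs + 0.3 * s.apgs + rng.normal(size=400)
        f1 = fit_anchor(Y, s, "free")
        f2 = fit_anchor(10.0 * Y, s, "free")
        assert f2.beta_eu == pytest.approx(10 * f1.beta_eu, rel=1e-6)
        assert f2.beta_af == pytest.approx(10 * f1.beta_af, rel=1e-6)
        assert f2.intercept == pytest.approx(10 * f1.intercept, rel=1e-6)
        assert f2.omega == pytest.approx(f1.omega, abs=1e-6)

    def test_omega_unidentifiable_flagged(self, rng):
        s = _scores(rng, n=200)
        gen = np.random.default_rng(0)
        Y = gen.normal(size=200)  # no score signal at all
        fit = fit_anchor(Y, s, "free")
        if not fit.omega_identifiable:
            assert np.isnan(fit.omega)


class TestBootstrap:
    def test_deterministic_with_seed(self, rng):
        s = _scores(rng, n=150)
        Y = 0.5 * s.epgs + rng.normal(size=150)
        a = bootstrap_fit(Y, s, n_boot=40, seed=5)
        b = bootstrap_fit(Y, s, n_boot=40, seed=5)
        assert a.ci["beta_eu"] == b.ci["beta_eu"]

    def test_noise_free_zero_width(self, rng):
        s = _scores(rng, n=100)
        Y = 1.0 + 2.0 * s.epgs + 0.5 * s.apgs
        fit = bootstrap_fit(Y, s, n_boot=30, seed=1)
        lo, hi = fit.ci["beta_eu"]
        assert hi - lo < 1e-8

    def test_n_boot_too_small_raises(self, rng):
        s = _scores(rng, n=50)
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_fit(rng.normal(size=50), s, n_boot=1, seed=0)


class TestBins:
    def test_bin_assignment(self):
        assert assign_bins([0.2])[0] == 0
        assert assign_bins([0.96])[0] == 4
        assert assign_bins([0.05])[0] == -1
        assert assign_bins([0.35])[0] == 0  # first bin closed on the right

    def test_top_bin_apgs_only(self, rng):
        theta = np.concatenate([np.full(100, 0.2), np.full(100, 0.97)])
        s = _scores(rng, n=200, theta=theta)
        Y = 0.5 * s.apgs + rng.normal(size=200)
        fits = bin_and_fit(Y, s, min_bin_size=30)
        assert np.isnan(fits[4].beta_eu)
        assert np.isfinite(fits[4].beta_af)
        assert np.isfinite(fits[0].beta_eu)

    def test_small_bin_skipped(self, rng):
        theta = np.full(60, 0.2)
        s = _scores(rng, n=60, theta=theta)
        fits = bin_and_fit(0.3 * s.epgs + rng.normal(size=60), s, min_bin_size=30)
        assert fits[0] is not None
        assert fits[1] is None and fits[2] is None


class TestEstimateRho:
    def _ref(self, beta, boot=None):
        return ReferenceSlope(
            beta=beta, delta_r2=0.1, ci_beta=(beta - 0.1, beta + 0.1),
            n=100, n_boot=0 if boot is None else len(boot),
            boot_beta=np.asarray(boot if boot is not None else []),
        )

    def _fit(self, beta_eu, omega=0.0, beta_af=0.5):
        from anchorpgs.anchor_core import AnchorFit
        return AnchorFit(
            intercept=0.0, beta_eu=beta_eu, beta_af=beta_af, omega=omega,
            omega_mode="free",
        )

    def test_unit_ratio(self):
        est = estimate_rho(self._fit(2.0), self._ref(2.0))
        assert est.rho == pytest.approx(1.0)

    def test_omega_zero_projection_equals_plain(self):
        est = estimate_rho(self._fit(2.0, omega=0.0), self._ref(2.0))
        assert est.rho_projected_af == pytest.approx(est.rho)

    def test_projection_value(self):
        est = estimate_rho(self._fit(2.0, omega=0.25), self._ref(2.0))
        assert est.rho_projected_af == pytest.approx(1.25)

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError, match="reference"):
            estimate_rho(self._fit(1.0), self._ref(0.0))

    def test_unstable_flag(self):
        ref = ReferenceSlope(beta=0.05, delta_r2=0.0, ci_beta=(-0.1, 0.2), n=50)
        est = estimate_rho(self._fit(1.0), ref)
        assert est.unstable


class TestPoolTraits:
    def _pair(self, beta_eu, beta_obs):
        from anchorpgs.anchor_core import AnchorFit
        f = AnchorFit(intercept=0, beta_eu=beta_eu, beta_af=0.2, omega=0,
                      omega_mode="fixed_zero")
        r = ReferenceSlope(beta=beta_obs, delta_r2=0.1)
        return (f, r)

    def test_single_trait(self):
        pooled, _ = pool_traits([self._pair(1.5, 2.0)], weighting="equal")
        assert pooled == pytest.approx(0.75)

    def test_identical_traits(self):
        pairs = [self._pair(1.2, 1.5)] * 5
        pooled, _ = pool_traits(pairs, weighting="equal")
        assert pooled == pytest.approx(0.8)

    def test_mean_ratio_oracle(self):
        # mean(1, 3) / mean(1, 1) = 2
        pooled, _ = pool_traits(
            [self._pair(1.0, 1.0), self._pair(3.0, 1.0)], weighting="equal"
        )
        assert pooled == pytest.approx(2.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="trait"):
            pool_traits([])


class TestDecomposePgs:
    def test_single_variant(self, rng):
        ceu = rng.normal(size=(10, 1))
        caf = rng.normal(size=(10, 1))
        variants = pd.DataFrame(
            {"chrom": "1", "pos": [100], "ref": "A", "alt": "G", "id": ["1:100:A:G"]}
        )
        w = PgsWeights(
            table=pd.DataFrame(
                {"variant": ["1:100:A:G"], "chrom": ["1"], "pos": [100],
                 "effect_allele": ["G"], "other_allele": ["A"], "weight": [1.7]}
            )
        )
        s = decompose_pgs(ceu, caf, w, variants, theta=np.full(10, 0.5))
        np.testing.assert_allclose(s.epgs, 1.7 * ceu[:, 0])
        np.testing.assert_allclose(s.apgs, 1.7 * caf[:, 0])

    def test_fully_european_has_zero_apgs(self, rng):
        # African-background centered dosages are identically 0 for an
        # unmasked 100% European genome, so the APGS must be 0
        caf = np.zeros((5, 3))
        ceu = rng.normal(size=(5, 3))
        variants = pd.DataFrame(
            {"chrom": "1", "pos": [1, 2, 3], "ref": "A", "alt": "G",
             "id": ["1:1:A:G", "1:2:A:G", "1:3:A:G"]}
        )
        w = PgsWeights(
            table=pd.DataFrame(
                {"variant": variants["id"], "chrom": "1", "pos": variants["pos"],
                 "effect_allele": "G", "other_allele": "A",
                 "weight": rng.normal(size=3)}
            )
        )
        s = decompose_pgs(ceu, caf, w, variants, theta=np.zeros(5))
        np.testing.assert_array_equal(s.apgs, 0.0)

    def test_no_overlap_raises(self, rng):
        variants = pd.DataFrame(
            {"chrom": "1", "pos": [1], "ref": "A", "alt": "G", "id": ["1:1:A:G"]}
        )
        w = PgsWeights(
            table=pd.DataFrame(
                {"variant": ["2:9:A:G"], "chrom": ["2"], "pos": [9],
                 "effect_allele": ["G"], "other_allele": ["A"], "weight": [1.0]}
            )
        )
        with pytest.raises(ValueError, match="overlap"):
            decompose_pgs(np.zeros((5, 1)), np.zeros((5, 1)), w, variants,
                          theta=np.zeros(5))
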