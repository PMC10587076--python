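"""GBLUP-AD Gibbs sampler, PC-BLUP, heritability and bivariate correlations."""

import numpy as np
import pytest

from phenogp.gblup import (
    MCMCConfig,
    NonPSDError,
    fit_bivariate,
    fit_gblup_ad,
    fit_pc_blup,
    genomic_heritability,
    heritability_of_fit,
    predict_masked,
)
from phenogp.genomics import RelationshipPair, pcoa

FAST = MCMCConfig(iterations=3000, burn_in=500, thinning=5, seed=0)


def identity_rel(n):
    return RelationshipPair(np.eye(n), None, 1.0, None, [f"H{i}" for i in range(n)])


def blup_oracle(y, g, sa2, se2):
    """Closed-form GLS/BLUP: mu by GLS, a = sa2 G V^-1 (y - mu)."""
    n = y.size
    v = sa2 * g + se2 * np.eye(n)
    vi = np.linalg.inv(v)
    one = np.ones(n)
    mu = (one @ vi @ y) / (one @ vi @ one)
    return mu, sa2 * g @ vi @ (y - mu)


class TestMCMCConfig:
    def test_profiles(self):
        paper = MCMCConfig.profile("published")
        assert (paper.iterations, paper.burn_in, paper.thinning) == (60000, 10000, 5)
        with pytest.raises(ValueError):
            MCMCConfig.profile("warp")

    def test_invalid_settings(self):
        with pytest.raises(ValueError):
            MCMCConfig(iterations=100, burn_in=200)
        with pytest.raises(ValueError):
            MCMCConfig(thinning=0)


class TestFitGblupAd:
    def test_zero_variance_trait_collapses_to_mean(self):
        n = 40
        y = np.full(n, 3.0)
        fit = fit_gblup_ad(y, identity_rel(n), FAST, dominance=False)
        prior_scale = max(1e-8, 0.0)
        assert fit.sigma_a2 < 5e-8  # < 5% of the (degenerate) prior scale
        np.testing.assert_allclose(fit.predicted, 3.0, atol=1e-3)

    def test_identity_grm_matches_ridge_oracle(self):
        """Fixed-ratio additive-only fit equals the closed-form BLUP."""
        rng = np.random.default_rng(1)
        n = 80
        y = rng.normal(0, 1, n)
        sa2, se2 = 0.6, 0.4
        cfg = MCMCConfig(iterations=20000, burn_in=4000, thinning=2, seed=3)
        fit = fit_gblup_ad(y, identity_rel(n), cfg, dominance=False, fix_variances=(sa2, se2))
        _, a_ref = blup_oracle(y, np.eye(n), sa2, se2)
        assert np.abs(fit.additive - a_ref).max() < 0.02 * y.std()

    def test_chain_seed_determinism(self, small_trait, small_rel):
        y, _ = small_trait
        f1 = fit_gblup_ad(y, small_rel, FAST)
        f2 = fit_gblup_ad(y, small_rel, FAST)
        assert f1.sigma_a2 == f2.sigma_a2
        np.testing.assert_array_equal(f1.predicted, f2.predicted)

    def test_range_shrinkage(self, small_trait, small_rel):
        """sd(predicted) < sd(observed) whenever h2 < 1."""
        y, _ = small_trait
        fit = fit_gblup_ad(y, small_rel, FAST)
        assert heritability_of_fit(fit) < 1.0
        assert fit.predicted.std() < y.std()

    def test_non_psd_matrix_advises_jitter(self):
        g = np.eye(10)
        g[0, 0] = -1.0
        rel = RelationshipPair(g, None, 1.0, None, [str(i) for i in range(10)])
        with pytest.raises(NonPSDError, match="jitter"):
            fit_gblup_ad(np.zeros(10), rel, FAST, dominance=False)

    def test_fixed_markers_capture_large_qtl(self, small_panel, small_trait, small_rel):
        y, _ = small_trait
        qtl = small_panel.codes[:, 10].astype(float)
        y_qtl = y + 3.0 * qtl
        fit = fit_gblup_ad(y_qtl, small_rel, FAST, fixed_markers=qtl[:, None])
        assert fit.beta[0] == pytest.approx(3.0, abs=0.8)

    def test_variance_monotone_in_simulated_signal(self, small_panel, small_rel):
        from phenogp.simulate import SimConfig, simulate_trait

        h2s = []
        for sa2 in (0.2, 0.5, 0.8):
            cfg = SimConfig(seed=21, sigma_a2=sa2, sigma_d2=0.0, sigma_e2=1.0 - sa2)
            obs, _ = simulate_trait(small_panel, cfg)
            y = obs[obs["environment"] == "env0"]["value"].to_numpy()
            fit = fit_gblup_ad(y, small_rel, FAST)
            h2s.append(heritability_of_fit(fit))
        assert h2s[0] < h2s[1] < h2s[2]
        assert all(0.0 <= h <= 1.0 for h in h2s)


class TestPredictMasked:
    def test_duplicate_hybrid_predicted_like_its_twin(self, small_panel):
        from phenogp.genomics import GenotypeMatrix, relationship_matrices
        from phenogp.simulate import SimConfig, simulate_trait

        codes = np.vstack([small_panel.codes, small_panel.codes[:1]]).astype(np.int8)
        ids = list(small_panel.hybrid_ids) + ["TWIN"]
        panel2 = GenotypeMatrix(codes, ids, list(small_panel.locus_ids))
        rel2 = relationship_matrices(panel2)
        cfg = SimConfig(seed=31, sigma_a2=0.7, sigma_d2=0.0, sigma_e2=0.1)
        obs, _ = simulate_trait(panel2, cfg)
        y = obs[obs["environment"] == "env0"]["value"].to_numpy().astype(float)
        y[-1] = np.nan  # mask the twin
        fit = fit_gblup_ad(y, rel2, FAST)
        twin_pred = predict_masked(fit)[0]
        assert twin_pred == pytest.approx(fit.predicted[0], abs=0.25 * np.nanstd(y))

    def test_no_masked_hybrids_errors(self, small_trait, small_rel):
        y, _ = small_trait
        fit = fit_gblup_ad(y, small_rel, FAST)
        with pytest.raises(ValueError, match="no masked"):
            predict_masked(fit)

    def test_null_heritability_gives_uninformative_predictions(self, small_panel, small_rel):
        from phenogp.simulate import SimConfig, simulate_trait

        rng = np.random.default_rng(99)
        rs = []
        for seed in range(20):
            cfg = SimConfig(seed=seed, sigma_a2=0.0, sigma_d2=0.0, sigma_e2=1.0)
            obs, _ = simulate_trait(small_panel, cfg)
            y = obs[obs["environment"] == "env0"]["value"].to_numpy()
            masked_idx = rng.choice(y.size, 20, replace=False)
            y_masked = y.copy()
            y_masked[masked_idx] = np.nan
            cfg_m = MCMCConfig(iterations=2000, burn_in=400, thinning=5, seed=seed)
            fit = fit_gblup_ad(y_masked, small_rel, cfg_m)
            rs.append(np.corrcoef(fit.predicted[masked_idx], y[masked_idx])[0, 1])
        assert abs(np.mean(rs)) < 0.12


class TestGenomicHeritability:
    def test_total_mode_reconstructs_published_style_components(self):
        assert genomic_heritability(3.66, 0.59, 0.95) == pytest.approx(0.82, abs=0.005)

    def test_additive_mode(self):
        assert genomic_heritability(0.6, 0.2, 0.2, mode="additive") == pytest.approx(0.6)

    def test_zero_residual(self):
        assert genomic_heritability(0.5, 0.5, 0.0) == 1.0

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            genomic_heritability(0.0, 0.0, 0.0)


class TestPCBlup:
    def test_trait_equal_to_first_axis(self, small_panel):
        coords, _ = pcoa(small_panel, 5)
        y = coords[:, 0].copy()
        fit = fit_pc_blup(y, coords)
        assert np.corrcoef(fit.predicted, y)[0, 1] > 0.999

    def test_residual_orthogonality(self, small_panel, small_trait):
        coords, _ = pcoa(small_panel, 5)
        y, _ = small_trait
        fit = fit_pc_blup(y, coords)
        resid = y - fit.predicted
        for k in range(5):
            assert abs(np.corrcoef(resid, coords[:, k])[0, 1]) < 1e-8

    def test_fewer_axes_warns(self, small_panel, small_trait):
        coords, _ = pcoa(small_panel, 3)
        y, _ = small_trait
        with pytest.warns(UserWarning, match="axes"):
            fit_pc_blup(y, coords[:, :3], n_axes=5)


class TestBivariate:
    def test_identical_traits_fully_correlated(self):
        # needs a panel large enough for the covariances to be identified
        from conftest import medium_setup

        _, rel, obs, _ = medium_setup(7, sigma_a2=0.6, sigma_d2=0.1, sigma_e2=0.3, n_snps=1000)
        y = obs[obs["environment"] == "env0"]["value"].to_numpy()
        cfg = MCMCConfig(iterations=6000, burn_in=1000, thinning=5, seed=0)
        fit = fit_bivariate(y, y.copy(), rel, cfg)
        assert fit.genetic_correlation > 0.95

    def test_independent_traits_uncorrelated(self, small_panel, small_rel):
        from phenogp.simulate import SimConfig, simulate_trait

        rgs = []
        for seed in range(6):
            o1, _ = simulate_trait(small_panel, SimConfig(seed=seed, sigma_d2=0.0))
            o2, _ = simulate_trait(small_panel, SimConfig(seed=seed + 100, sigma_d2=0.0))
            y1 = o1[o1["environment"] == "env0"]["value"].to_numpy()
            y2 = o2[o2["environment"] == "env0"]["value"].to_numpy()
            cfg = MCMCConfig(iterations=2000, burn_in=400, thinning=5, seed=seed)
            rgs.append(fit_bivariate(y1, y2, small_rel, cfg).genetic_correlation)
        assert abs(np.mean(rgs)) < 0.25

    def test_disjoint_observation_sets_error(self, small_trait, small_rel):
        y, _ = small_trait
        y1 = y.copy()
        y2 = y.copy()
        y1[: y.size // 2] = np.nan
        y2[y.size // 2 :] = np.nan
        with pytest.raises(ValueError, match="shared"):
            fit_bivariate(y1, y2, small_rel, FAST)

    def test_minimum_shared_hybrids_enforced(self, small_trait, small_rel):
        y, _ = small_trait
        y1 = np.full_like(y, np.nan)
        y1[:10] = y[:10]
        with pytest.raises(ValueError, match="need >= 15"):
            fit_bivariate(y1, y, small_rel, FAST)
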