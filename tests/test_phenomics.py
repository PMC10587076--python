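"""Thermal time, LAR/LER extraction, growth splines and spatial adjustment."""

import numpy as np
import pandas as pd
import pytest

from phenogp.phenomics import (
    ThermalClock,
    extract_lar,
    extract_ler,
    fit_growth_spline,
    spatial_correct,
    thermal_time,
    vegetative_phase_duration,
)
from phenogp.simulate import simulate_env_series, simulate_field_trial, simulate_growth_series


def const_env(hours, temp):
    return pd.DataFrame({"temperature_C": np.full(hours, float(temp))})


class TestThermalTime:
    def test_normalization_at_20(self):
        assert thermal_time(const_env(24, 20.0))[-1] == pytest.approx(1.0, abs=1e-12)

    def test_half_rate_temperature(self):
        # linear response, base 8: f(14) = 0.5 f(20)
        assert thermal_time(const_env(24, 14.0))[-1] == pytest.approx(0.5, abs=1e-12)

    def test_mixed_day_hand_sum(self):
        env = pd.DataFrame({"temperature_C": np.r_[np.full(12, 20.0), np.full(12, 14.0)]})
        assert thermal_time(env)[-1] == pytest.approx(0.75, abs=1e-12)

    def test_additive_over_segments(self):
        env = simulate_env_series(6, "mild", seed=1)
        tt_full = thermal_time(env)[-1]
        tt_a = thermal_time(env.iloc[: 3 * 24])[-1]
        tt_b = thermal_time(env.iloc[3 * 24 :].reset_index(drop=True))[-1]
        assert tt_full == pytest.approx(tt_a + tt_b, abs=1e-10)

    def test_out_of_domain_clipped_with_warning(self):
        clock = ThermalClock()
        with pytest.warns(UserWarning, match="clipped"):
            w = clock.weights(np.array([-5.0, 50.0]))
        assert (w >= 0).all()

    def test_gap_interpolation_limit(self):
        temp = np.full(48, 20.0)
        temp[10:13] = np.nan  # 3 h gap: interpolated
        assert thermal_time(pd.DataFrame({"temperature_C": temp}))[-1] == pytest.approx(2.0)
        temp[10:15] = np.nan  # 5 h gap: rejected
        with pytest.raises(ValueError, match="gap"):
            thermal_time(pd.DataFrame({"temperature_C": temp}))

    def test_beta_response_also_normalizes(self):
        clock = ThermalClock(response="beta")
        assert clock.weights(np.array([20.0]))[0] == pytest.approx(1.0)
        assert clock.weights(np.array([30.0]))[0] > 1.0


class TestExtractLar:
    def test_noiseless_linear_counts(self):
        tt = np.arange(0.0, 50.0, 3.5)
        counts = 2.0 + 0.25 * tt
        assert extract_lar(counts, tt) == pytest.approx(0.25, abs=1e-12)

    def test_noisy_recovery_envelope(self):
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            tt = np.arange(0.0, 45.0, 6.0)
            counts = 2.0 + 0.25 * tt + rng.normal(0, 0.5, tt.size)
            if abs(extract_lar(counts, tt) - 0.25) <= 0.05:
                hits += 1
        assert hits / n_rep > 0.9

    def test_window_after_twelve_leaves_is_missing(self):
        tt = np.array([50.0, 55.0, 60.0])
        counts = np.array([14.0, 15.0, 16.0])
        assert np.isnan(extract_lar(counts, tt))

    def test_too_few_points_missing_not_crash(self):
        assert np.isnan(extract_lar(np.array([2.0, 5.0]), np.array([0.0, 10.0])))


class TestGrowthSpline:
    def test_cubic_polynomial_oracle(self):
        t = np.linspace(0, 40, 30)
        y = 0.01 * t**3 - 0.3 * t**2 + 5 * t + 2
        curve = fit_growth_spline(t, y)
        err = np.abs(curve(t) - y).max()
        assert err < 1e-3 * (y.max() - y.min())

    def test_constant_series_flat_derivative(self):
        t = np.linspace(0, 30, 20)
        curve = fit_growth_spline(t, np.full(20, 7.0))
        assert np.abs(curve.derivative(t)).max() < 1e-6 * 7.0

    def test_offset_plants_average(self):
        t = np.linspace(0, 30, 15)
        base = 2.0 * t
        c = 3.0
        times = np.r_[t, t]
        values = np.r_[base + c, base - c]
        curve = fit_growth_spline(times, values)
        assert np.abs(curve(t) - base).max() < c


class TestExtractLer:
    def test_linear_growth_both_methods(self):
        t = np.linspace(10, 60, 60)
        curve = fit_growth_spline(t, 150.0 * t)
        assert extract_ler(curve, method="max_derivative") == pytest.approx(150.0, rel=1e-3)
        assert extract_ler(curve, method="window_slope") == pytest.approx(150.0, rel=1e-3)

    def test_logistic_analytic_max_slope(self):
        # A(t) = Amax/(1+exp(-k(t-t0))): max slope Amax*k/4 at t0
        a_max, k, t0 = 2700.0, 0.2, 34.0
        t = np.linspace(5, 70, 120)
        curve = fit_growth_spline(t, a_max / (1.0 + np.exp(-k * (t - t0))))
        analytic = a_max * k / 4.0
        assert extract_ler(curve, method="max_derivative") == pytest.approx(analytic, rel=0.02)

    def test_window_slope_below_max_derivative_for_saturating_curve(self):
        t = np.linspace(5, 70, 120)
        curve = fit_growth_spline(t, 3000.0 / (1.0 + np.exp(-0.15 * (t - 30.0))))
        assert extract_ler(curve, method="window_slope") <= extract_ler(
            curve, method="max_derivative"
        )

    def test_window_outside_support_missing(self):
        t = np.linspace(50, 70, 30)
        curve = fit_growth_spline(t, 10.0 * t)
        assert np.isnan(extract_ler(curve, window=(24.0, 45.0)))

    def test_round_trip_from_generator(self):
        env = simulate_env_series(80, "constant20")
        gs = simulate_growth_series(0.3, 150.0, 18, env)
        la = gs[gs["variable"] == "leaf_area"]
        curve = fit_growth_spline(la["thermal_time"].to_numpy(), la["value"].to_numpy())
        assert extract_ler(curve) == pytest.approx(150.0, rel=0.05)


class TestVegetativePhase:
    def test_constant_20(self):
        env = simulate_env_series(70, "constant20")
        assert vegetative_phase_duration(0, 60, env) == pytest.approx(60.0, abs=1e-10)

    def test_half_rate_temperature(self):
        env = pd.DataFrame({"temperature_C": np.full(60 * 24, 14.0)})
        assert vegetative_phase_duration(0, 60, env) == pytest.approx(30.0, abs=1e-10)

    def test_anthesis_before_emergence(self):
        env = simulate_env_series(10, "constant20")
        with pytest.raises(ValueError, match="after emergence"):
            vegetative_phase_duration(5, 3, env)

    def test_missing_coverage_named(self):
        env = simulate_env_series(10, "constant20")
        with pytest.raises(ValueError, match="outside"):
            vegetative_phase_duration(0, 30, env)


class TestSpatialCorrect:
    def test_no_spatial_effects_blues_equal_raw_means(self):
        gv = np.arange(20.0)
        # noise-free balanced design: the model collapses exactly
        plots = simulate_field_trial(
            gv, n_rep=3, rows=6, cols=10, spatial_fraction=0.0, residual_sd=0.0, seed=4
        )
        adj = spatial_correct(plots)
        raw = plots.groupby("genotype")["value"].mean()
        merged = adj.blues.set_index("genotype").join(raw.rename("raw"))
        sd = plots["value"].std()
        assert np.abs(merged["blue"] - merged["raw"]).max() < 1e-6 * sd
        # with plot noise the BLUEs stay statistically close to raw means
        noisy = simulate_field_trial(
            gv, n_rep=3, rows=6, cols=10, spatial_fraction=0.0, residual_sd=0.3, seed=4
        )
        adj_n = spatial_correct(noisy)
        raw_n = noisy.groupby("genotype")["value"].mean()
        merged_n = adj_n.blues.set_index("genotype").join(raw_n.rename("raw"))
        assert np.abs(merged_n["blue"] - merged_n["raw"]).max() < 0.05 * noisy["value"].std()

    def test_surface_recovery_beats_raw_means(self):
        wins = 0
        for seed in range(6):
            rng = np.random.default_rng(seed)
            gv = rng.normal(0, 1, 56)
            plots = simulate_field_trial(
                gv, n_rep=3, rows=12, cols=14, spatial_fraction=0.7,
                residual_sd=1.2, seed=seed,
            )
            adj = spatial_correct(plots)
            ids = [f"H{i:04d}" for i in range(56)]
            blue = adj.blues.set_index("genotype").loc[ids, "blue"].to_numpy()
            raw = plots.groupby("genotype")["value"].mean().loc[ids].to_numpy()
            if np.corrcoef(blue, gv)[0, 1] >= np.corrcoef(raw, gv)[0, 1]:
                wins += 1
        assert wins >= 5

    def test_pure_noise_heritability_near_zero(self):
        """Plot-level H2 of a pure-noise trait stays below 0.15 almost always;
        the line-mean form (divided replicate variance) is noisier but bounded."""
        small_plot = 0
        line_vals = []
        n_seeds = 15
        for seed in range(n_seeds):
            plots = simulate_field_trial(
                np.zeros(100), n_rep=3, rows=15, cols=20, spatial_fraction=0.0,
                residual_sd=1.0, seed=100 + seed,
            )
            adj = spatial_correct(plots)
            if adj.heritability_plot < 0.15:
                small_plot += 1
            line_vals.append(adj.heritability)
        assert small_plot >= int(0.9 * n_seeds)
        assert np.mean(line_vals) < 0.15

    def test_unreplicated_design_flags_heritability(self):
        gv = np.arange(12.0)
        plots = simulate_field_trial(gv, n_rep=1, rows=3, cols=4, seed=0)
        adj = spatial_correct(plots)
        assert adj.heritability is None
        assert len(adj.blues) == 12

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            spatial_correct(pd.DataFrame({"genotype": ["a"], "value": [1.0]}))
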