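"""Thermal time, longitudinal trait extraction and spatial adjustment.

Developmental traits are expressed per equivalent day at 20 deg C
(d_20C): each hour contributes f(T)/f(20)/24 to thermal time, where f is
a temperature-response function normalized so f(20) = 1.

* LAR (leaf appearance rate, leaves per d_20C) is the OLS slope of
  visible leaf number against thermal time from emergence to the 12-leaf
  stage.
* LER (maximum leaf expansion rate, cm^2 per d_20C) is extracted from a
  penalized-spline fit of whole-plant leaf area against thermal time,
  either as the maximum of the fitted derivative over a 24-45 d_20C
  window or as the OLS slope of the fitted values across that window.
* Plot-level traits are spatially adjusted with a mixed model (fixed
  genotype, random rows, random columns, smooth tensor-product spline
  surface); BLUEs come from the fixed-genotype fit and broad-sense
  heritability from the random-genotype refit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .mixedmodel import fit_reml, tensor_surface_basis

logger = logging.getLogger(__name__)

LER_WINDOW = (24.0, 45.0)  # d_20C after emergence
TWELVE_LEAF = 12.0


@dataclass
class ThermalClock:
    """Temperature-response function normalized at 20 deg C.

    "linear": f rises linearly from t_base to t_opt, then falls linearly
    to zero at t_max. "beta": the beta response of crop phenology models,
    g(T) = ((t_max-T)/(t_max-t_opt)) * ((T-t_base)/(t_opt-t_base))^c with
    c = (t_opt-t_base)/(t_max-t_opt). Both are clipped to zero outside
    [t_base, t_max]; weights are g(T)/g(20).
    """

    response: str = "linear"
    t_base: float = 8.0
    t_opt: float = 30.0
    t_max: float = 44.0

    def __post_init__(self) -> None:
        if not self.t_base < 20.0 < self.t_opt < self.t_max:
            raise ValueError("need t_base < 20 < t_opt < t_max")
        if self.response not in ("linear", "beta"):
            raise ValueError("response must be 'linear' or 'beta'")

    def _raw(self, temp: np.ndarray) -> np.ndarray:
        t = np.clip(temp, self.t_base, self.t_max)
        if self.response == "linear":
            rising = t - self.t_base
            falling = (self.t_max - t) / (self.t_max - self.t_opt) * (
                self.t_opt - self.t_base
            )
            return np.where(t <= self.t_opt, rising, falling)
        c = (self.t_opt - self.t_base) / (self.t_max - self.t_opt)
        with np.errstate(invalid="ignore"):
            g = ((self.t_max - t) / (self.t_max - self.t_opt)) * (
                (t - self.t_base) / (self.t_opt - self.t_base)
            ) ** c
        return np.nan_to_num(g)

    def weights(self, temp_c: np.ndarray) -> np.ndarray:
        """f(T)/f(20), clipping out-of-domain temperatures with a warning."""
        temp_c = np.asarray(temp_c, dtype=float)
        out = (temp_c < self.t_base) | (temp_c > self.t_max)
        if out.any():
            warnings.warn(
                f"{int(out.sum())} temperatures outside [{self.t_base}, {self.t_max}] "
                "clipped to the response domain",
                stacklevel=2,
            )
        return self._raw(temp_c) / self._raw(np.array(20.0))


def thermal_time(env: pd.DataFrame, clock: ThermalClock | None = None) -> np.ndarray:
    """Cumulative equivalent days at 20 deg C over an hourly series.

    Gaps of up to 3 hours in temperature are linearly interpolated; larger
    gaps raise. Returns the cumulative sum of f(T_h)/f(20)/24.
    """
    clock = clock or ThermalClock()
    temp = pd.Series(np.asarray(env["temperature_C"], dtype=float))
    if temp.isna().any():
        runs = temp.isna().astype(int).groupby(temp.notna().cumsum()).sum()
        if runs.max() > 3:
            raise ValueError(f"temperature gap of {int(runs.max())} h exceeds 3 h")
        temp = temp.interpolate(limit_direction="both")
    w = clock.weights(temp.to_numpy())
    return np.cumsum(w) / 24.0


def vegetative_phase_duration(
    emergence_day: int, anthesis_day: int, env: pd.DataFrame, clock: ThermalClock | None = None
) -> float:
    """Thermal time (d_20C) between emergence and anthesis."""
    if anthesis_day <= emergence_day:
        raise ValueError("anthesis must come after emergence")
    n_days = len(env) // 24
    if anthesis_day > n_days:
        raise ValueError(
            f"environment series covers {n_days} days; anthesis day {anthesis_day} outside"
        )
    tt = thermal_time(env, clock)
    start = emergence_day * 24 - 1
    start_tt = tt[start] if start >= 0 else 0.0
    return float(tt[anthesis_day * 24 - 1] - start_tt)


def extract_lar(
    counts: np.ndarray,
    thermal_times: np.ndarray,
    emergence_leaf: float = 1.0,
    end_leaf: float = TWELVE_LEAF,
) -> float:
    """LAR as the OLS slope of leaf number vs thermal time up to 12 leaves.

    The window runs from the first observation with >= ``emergence_leaf``
    visible leaves to the first observation at or past ``end_leaf``
    (included, since weekly scoring makes the exact crossing unobservable).
    Returns NaN with a log message when fewer than 3 observations fall in
    the window.
    """
    counts = np.asarray(counts, dtype=float)
    thermal_times = np.asarray(thermal_times, dtype=float)
    started = counts >= emergence_leaf
    if not started.any():
        logger.warning("extract_lar: no observation at or past emergence")
        return float("nan")
    first = int(np.argmax(started))
    past = np.where(counts >= end_leaf)[0]
    last = int(past[0]) if past.size else len(counts) - 1
    window = slice(first, last + 1)
    t, c = thermal_times[window], counts[window]
    if t.size < 3:
        logger.warning("extract_lar: only %d observations in window; skipped", t.size)
        return float("nan")
    slope = np.polyfit(t, c, 1)[0]
    logger.debug("extract_lar window: tt %.1f-%.1f, %d points", t[0], t[-1], t.size)
    return float(slope)


@dataclass
class GrowthCurve:
    """Penalized-spline fit of one genotype's growth series."""

    spline: object
    support: tuple[float, float]

    def __call__(self, t):
        return self.spline(np.asarray(t, dtype=float))

    def derivative(self, t):
        return self.spline.derivative()(np.asarray(t, dtype=float))


def fit_growth_spline(
    times: np.ndarray, values: np.ndarray, lam: float | None = None
) -> GrowthCurve:
    """Smoothing-spline fit of pooled (thermal time, value) observations.

    Observations from several plants of one genotype are pooled; repeated
    time points are averaged (the genotype curve is the plant mean, per
    the additive per-plant-intercept model). The penalty is chosen by
    generalized cross-validation unless ``lam`` is given. Falls back to a
    lower-order polynomial when fewer than 6 distinct times are available.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(times)
    times, values = times[order], values[order]
    uniq, inv = np.unique(times, return_inverse=True)
    mean_vals = np.bincount(inv, weights=values) / np.bincount(inv)
    if uniq.size < 6:
        logger.warning(
            "fit_growth_spline: %d distinct times < 6; polynomial fallback", uniq.size
        )
        deg = max(uniq.size - 2, 1)
        poly = np.polynomial.Polynomial.fit(uniq, mean_vals, deg)

        class _P:
            def __call__(self, t):
                return poly(t)

            def derivative(self):
                d = poly.deriv()
                return lambda t: d(t)

        return GrowthCurve(_P(), (float(uniq[0]), float(uniq[-1])))
    spline = make_smoothing_spline(uniq, mean_vals, lam=lam)
    return GrowthCurve(spline, (float(uniq[0]), float(uniq[-1])))


def extract_ler(
    curve: GrowthCurve,
    window: tuple[float, float] = LER_WINDOW,
    method: str = "max_derivative",
) -> float:
    """Maximum leaf expansion rate over the 24-45 d_20C window.

    "max_derivative": maximum of the fitted first derivative on the
    window; "window_slope": OLS slope of fitted values across the window.
    Returns NaN when the window lies outside the curve's support.
    """
    if method not in ("max_derivative", "window_slope"):
        raise ValueError("method must be 'max_derivative' or 'window_slope'")
    lo, hi = window
    s_lo, s_hi = curve.support
    if hi <= s_lo or lo >= s_hi:
        logger.warning("extract_ler: window [%s, %s] outside support", lo, hi)
        return float("nan")
    lo, hi = max(lo, s_lo), min(hi, s_hi)
    grid = np.linspace(lo, hi, 211)
    if method == "max_derivative":
        return float(np.max(curve.derivative(grid)))
    fitted = curve(grid)
    return float(np.polyfit(grid, fitted, 1)[0])


@dataclass
class AdjustedTrait:
    """Spatially adjusted genotype means with the experiment heritability.

    ``heritability`` is the line-mean ratio s2_g / (s2_g + s2_e / n_rep);
    ``heritability_plot`` is the plot-level ratio s2_g / (s2_g + s2_e).
    """

    blues: pd.DataFrame  # genotype, blue, se
    heritability: float | None
    heritability_plot: float | None
    sigma2_geno: float | None
    sigma2_resid: float
    n_rep: float


def spatial_correct(
    plots: pd.DataFrame,
    value_col: str = "value",
    n_surface_basis: int = 6,
    heritability: bool = True,
) -> AdjustedTrait:
    """BLUEs and broad-sense H2 from a spatial mixed model.

    Fixed genotype effects (cell means), random row and column effects and
    a random tensor-product B-spline surface on (row, column); variance
    components by REML. H2 = s2_g / (s2_g + s2_e / n_rep) from the refit
    with genotype random, with n_rep the harmonic mean of per-genotype
    replicate counts. H2 is None for unreplicated designs.
    """
    required = {"genotype", "row", "column", value_col}
    missing = required - set(plots.columns)
    if missing:
        raise ValueError(f"plot table missing columns: {sorted(missing)}")
    plots = plots.reset_index(drop=True)
    y = plots[value_col].to_numpy(dtype=float)
    genos = pd.Categorical(plots["genotype"])
    x = pd.get_dummies(genos).to_numpy(dtype=float)  # cell means: BLUE per genotype
    reps = plots.groupby("genotype").size()
    n_rep = float(len(reps) / (1.0 / reps).sum())  # harmonic mean
    if x.shape[1] >= len(y):
        # no residual degrees of freedom (unreplicated): raw values are the BLUEs
        logger.warning("spatial_correct: no residual df; returning raw genotype means")
        raw = plots.groupby("genotype")[value_col].mean()
        blues = pd.DataFrame(
            {"genotype": raw.index, "blue": raw.to_numpy(), "se": np.nan}
        )
        return AdjustedTrait(blues, None, None, None, float("nan"), n_rep)
    z_row = pd.get_dummies(plots["row"]).to_numpy(dtype=float)
    z_col = pd.get_dummies(plots["column"]).to_numpy(dtype=float)
    z_surf = tensor_surface_basis(
        plots["row"].to_numpy(float), plots["column"].to_numpy(float), n_surface_basis, n_surface_basis
    )
    fit = fit_reml(y, x, [z_row, z_col, z_surf])
    blues = pd.DataFrame(
        {
            "genotype": genos.categories,
            "blue": fit.beta,
            "se": np.sqrt(np.diag(fit.beta_cov)),
        }
    )
    h2 = h2_plot = s2g = None
    s2e = fit.sigma2_e
    if heritability and reps.min() >= 2:
        xr = np.ones((len(y), 1))
        fit_r = fit_reml(y, xr, [x, z_row, z_col, z_surf])
        s2g = fit_r.sigma2[0]
        s2e = fit_r.sigma2_e
        h2 = s2g / (s2g + s2e / n_rep)
        h2_plot = s2g / (s2g + s2e)
    elif heritability:
        logger.warning("spatial_correct: unreplicated design; heritability unavailable")
    return AdjustedTrait(blues, h2, h2_plot, s2g, s2e, n_rep)
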