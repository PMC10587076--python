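"""Environment-based trait translation: Penman-Monteith inversion,
stomatal conductance under saturating light, environment-response lines
and a simplified daily crop loop producing leaf area index (LAI).

Whole-plant stomatal conductance is obtained by inverting the big-leaf
Penman-Monteith equation for surface conductance given observed
transpiration, net radiation, temperature, VPD and boundary-layer
conductance. The forward/inverse pair is algebraically exact, so the
round trip reproduces the conductance to numerical precision.

The LAI simulator is deliberately lightweight: leaves are initiated at
rate LAR in thermal time, each expands at LER_max scaled down by linear
VPD and soil-water-potential stress factors for a fixed thermal
duration, capped by a rank-dependent potential area. It is a simulator
convention, not a reimplementation of a full crop model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .simulate import saturation_vapor_pressure

logger = logging.getLogger(__name__)

CP_AIR = 1010.0  # J kg-1 K-1
RD = 287.05  # J kg-1 K-1, dry air gas constant
RGAS = 8.314  # J mol-1 K-1
PRESSURE_KPA = 101.325
MW_WATER = 0.018015  # kg mol-1
GAMMA_KPA = 0.0665  # psychrometric constant at standard pressure


class NonPhysicalFluxError(ValueError):
    """Observed transpiration exceeds the infinite-conductance PM limit."""


@dataclass
class PlantFluxRecord:
    """One transpiration observation used for conductance inversion."""

    transpiration: float  # mmol H2O m-2 s-1 (leaf-area basis)
    net_radiation: float  # W m-2
    temp_c: float
    vpd_kpa: float
    g_boundary: float  # mmol m-2 s-1

    def __post_init__(self) -> None:
        if self.vpd_kpa < 0:
            raise ValueError("VPD must be >= 0")
        if self.g_boundary <= 0:
            raise ValueError("boundary-layer conductance must be > 0")


def transpiration_flux(grams_per_hour: float, leaf_area_m2: float) -> float:
    """Convert plant water loss (g/h) over a leaf area (m^2) to mmol m-2 s-1."""
    if leaf_area_m2 <= 0:
        raise ValueError("leaf area must be > 0")
    mol_per_s = grams_per_hour / 3600.0 / (MW_WATER * 1000.0) / leaf_area_m2
    return mol_per_s * 1000.0  # mol -> mmol


def _pm_terms(temp_c: float):
    t_k = temp_c + 273.15
    es = saturation_vapor_pressure(temp_c)
    # Tetens derivative: d es/dT
    delta = es * 17.27 * 237.3 / (temp_c + 237.3) ** 2
    lam = 2.501e6 - 2361.0 * temp_c  # J kg-1
    rho = PRESSURE_KPA * 1000.0 / (RD * t_k)  # kg m-3
    mol_to_ms = RGAS * t_k / (PRESSURE_KPA * 1000.0)  # m s-1 per mol m-2 s-1
    return delta, lam, rho, mol_to_ms


def penman_monteith_forward(
    gs: float, net_radiation: float, temp_c: float, vpd_kpa: float, g_boundary: float
) -> float:
    """Big-leaf PM transpiration (mmol H2O m-2 s-1) at surface conductance gs.

    Conductances in mmol m-2 s-1.
    """
    if gs <= 0:
        return 0.0
    delta, lam, rho, mol_to_ms = _pm_terms(temp_c)
    ga_ms = g_boundary / 1000.0 * mol_to_ms
    gs_ms = gs / 1000.0 * mol_to_ms
    num = delta * net_radiation + rho * CP_AIR * ga_ms * vpd_kpa
    le = num / (delta + GAMMA_KPA * (1.0 + ga_ms / gs_ms))
    return le / lam / MW_WATER * 1000.0  # W m-2 -> mmol m-2 s-1


def invert_penman_monteith(rec: PlantFluxRecord) -> float:
    """Surface (stomatal) conductance, mmol m-2 s-1, solving PM for gs.

    Raises NonPhysicalFluxError when the observed transpiration exceeds
    the gs -> infinity limit of the PM equation, and ValueError when both
    VPD and radiation are zero (conductance undefined).
    """
    e = rec.transpiration
    if e <= 0:
        return 0.0
    if rec.vpd_kpa == 0 and rec.net_radiation == 0:
        raise ValueError("zero VPD and zero radiation: conductance undefined")
    delta, lam, rho, mol_to_ms = _pm_terms(rec.temp_c)
    ga_ms = rec.g_boundary / 1000.0 * mol_to_ms
    le = e / 1000.0 * MW_WATER * lam  # mmol m-2 s-1 -> W m-2
    num = delta * rec.net_radiation + rho * CP_AIR * ga_ms * rec.vpd_kpa
    denom = num / le - delta - GAMMA_KPA
    if denom <= 0:
        raise NonPhysicalFluxError(
            "transpiration exceeds the infinite-conductance Penman-Monteith limit"
        )
    gs_ms = GAMMA_KPA * ga_ms / denom
    return gs_ms / mol_to_ms * 1000.0


SATURATING_PPFD = 800.0  # umol m-2 s-1


def estimate_gs_max(
    gs: np.ndarray,
    light: np.ndarray,
    method: str = "hyperbola",
    saturation_threshold: float = SATURATING_PPFD,
    quantile: float = 0.9,
) -> float:
    """Stomatal conductance under saturating light for one genotype.

    "hyperbola" fits gs = gs_max * I / (I + K) and returns the asymptote;
    "quantile" returns the given quantile of conductances observed at
    light >= ``saturation_threshold``. Returns NaN with a log message
    when no high-light observations exist.
    """
    gs = np.asarray(gs, dtype=float)
    light = np.asarray(light, dtype=float)
    if gs.size < 8:
        raise ValueError("need at least 8 conductance-light pairs")
    if light.max() < saturation_threshold:
        logger.warning("estimate_gs_max: no observation at saturating light")
        return float("nan")
    if method == "quantile":
        high = gs[light >= saturation_threshold]
        return float(np.quantile(high, quantile))
    if method != "hyperbola":
        raise ValueError("method must be 'hyperbola' or 'quantile'")

    def hyperbola(i, g_max, k):
        return g_max * i / (i + k)

    p0 = (max(gs.max(), 1e-6), max(np.median(light), 1.0))
    popt, _ = curve_fit(hyperbola, light, gs, p0=p0, maxfev=10000)
    return float(popt[0])


@dataclass
class EnvResponse:
    """OLS line of experiment-mean trait values against one environment driver."""

    slope: float
    intercept: float
    r: float
    residuals: np.ndarray

    def predict(self, env_value):
        return self.intercept + self.slope * np.asarray(env_value, dtype=float)


def fit_env_response(
    trait_means: np.ndarray,
    env_values: np.ndarray,
    fit_subset: np.ndarray | None = None,
) -> EnvResponse:
    """Linear trait-vs-environment response across experiments.

    The line is fitted on the experiments flagged by ``fit_subset`` (for
    indoor-to-field translation: the field experiments); residuals are
    reported for all experiments against that single line, so indoor
    points are judged against the field relationship rather than fitted
    separately.
    """
    trait_means = np.asarray(trait_means, dtype=float)
    env_values = np.asarray(env_values, dtype=float)
    mask = (
        np.ones(trait_means.size, dtype=bool)
        if fit_subset is None
        else np.asarray(fit_subset, dtype=bool)
    )
    if mask.sum() < 3:
        raise ValueError("need at least 3 experiments to fit a response line")
    slope, intercept = np.polyfit(env_values[mask], trait_means[mask], 1)
    r = float(np.corrcoef(env_values[mask], trait_means[mask])[0, 1])
    residuals = trait_means - (intercept + slope * env_values)
    return EnvResponse(float(slope), float(intercept), r, residuals)


@dataclass
class GenotypeCropParams:
    """Indoor genotypic values that parameterize the LAI loop."""

    lar: float  # leaves per d_20C
    ler_max: float  # cm^2 per d_20C, per expanding leaf
    vpd_slope: float = -0.15  # fractional growth change per kPa above reference
    psi_slope: float = 0.8  # fractional growth change per MPa above reference
    final_leaf_number: int = 16

    def __post_init__(self) -> None:
        if self.lar <= 0 or self.ler_max < 0:
            raise ValueError("lar must be > 0 and ler_max >= 0")
        if self.final_leaf_number < 1:
            raise ValueError("final_leaf_number must be >= 1")


def simulate_lai(
    params: GenotypeCropParams,
    env: pd.DataFrame,
    density: float = 9.0,
    vpd_ref: float = 1.0,
    psi_ref: float = -0.05,
    leaf_duration: float = 16.0,  # d_20C of expansion per leaf
    rank_potential: np.ndarray | None = None,
    clock=None,
) -> tuple[pd.DataFrame, float]:
    """Daily LAI from indoor traits plus the field environment.

    Each leaf initiates at thermal time rank/LAR and expands for
    ``leaf_duration`` d_20C at LER_max scaled by
    max(0, 1 + vpd_slope*(VPD - vpd_ref)) * max(0, 1 + psi_slope*(psi - psi_ref)),
    capped at a rank-dependent potential area (default: generous bell
    profile over rank). LAI = plant area (cm^2) * density / 1e4.

    Returns the daily series (day, lai) and the LAI at flowering (end of
    leaf initiation plus one leaf duration).
    """
    if density <= 0:
        raise ValueError("density must be > 0")
    from .phenomics import ThermalClock, thermal_time

    clock = clock or ThermalClock()
    tt = thermal_time(env, clock)
    n_days = len(env) // 24
    if n_days < 1:
        raise ValueError("environment series shorter than one day")
    ranks = np.arange(1, params.final_leaf_number + 1)
    init_tt = ranks / params.lar
    if rank_potential is None:
        peak = 0.7 * params.final_leaf_number
        width = 0.35 * params.final_leaf_number
        rank_potential = 1000.0 * np.exp(-(((ranks - peak) / width) ** 2))
    areas = np.zeros(params.final_leaf_number)
    n_clamped = 0
    day_rows = []
    env_day = env.assign(_tt=tt, _day=np.arange(len(env)) // 24)
    daylight = env_day[env_day["ppfd"] > 0] if (env_day["ppfd"] > 0).any() else env_day
    vpd_daily = daylight.groupby("_day")["vpd_kPa"].mean().reindex(range(n_days)).ffill()
    psi_daily = env_day.groupby("_day")["soil_water_potential_MPa"].mean()
    tt_end = env_day.groupby("_day")["_tt"].last().to_numpy()
    tt_start = np.r_[0.0, tt_end[:-1]]
    flowering_tt = init_tt[-1] + leaf_duration
    lai_flowering = None
    for d in range(n_days):
        dtt = tt_end[d] - tt_start[d]
        stress = max(0.0, 1.0 + params.vpd_slope * (vpd_daily.iloc[d] - vpd_ref)) * max(
            0.0, 1.0 + params.psi_slope * (psi_daily.iloc[d] - psi_ref)
        )
        if stress == 0.0:
            n_clamped += 1
        # thermal-time overlap of each leaf's expansion window with this day
        lo = np.maximum(init_tt, tt_start[d])
        hi = np.minimum(init_tt + leaf_duration, tt_end[d])
        active_tt = np.maximum(hi - lo, 0.0)
        areas = np.minimum(areas + params.ler_max * stress * active_tt, rank_potential)
        lai = areas.sum() * density / 1e4
        day_rows.append((d, lai))
        if lai_flowering is None and tt_end[d] >= flowering_tt:
            lai_flowering = lai
    if n_clamped:
        logger.info("simulate_lai: expansion clamped to 0 on %d days", n_clamped)
    series = pd.DataFrame(day_rows, columns=["day", "lai"])
    if lai_flowering is None:
        lai_flowering = float(series["lai"].iloc[-1])
    return series, float(lai_flowering)
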