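"""Synthetic hybrid panels, traits, environments, trials and growth series.

Every generator is seeded and returns its ground truth separately from the
observables, so each downstream stage (trait extraction, spatial adjustment,
relationship matrices, GBLUP, cross-validation) has a parameter-recovery
test that needs no external data.

The default panel emulates a maize diversity panel built by crossing a
common (flint) tester to structured dent lines from four genetic groups;
group divergence follows a Balding-Nichols drift model on the ancestral
allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomics import GenotypeMatrix, additive_coding, dominance_coding

#: group sizes emulating the Iodent / Lancaster / Stiff-Stalk / diverse-dent split
DEFAULT_GROUP_SIZES = (39, 45, 55, 107)
DEFAULT_GROUP_NAMES = ("iodent", "lancaster", "stiff_stalk", "diverse_dent")

ENV_PROFILES = ("constant20", "mild", "hot_dry", "cool")


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the structure the analysis assumes: a ~246-hybrid
    tester x line panel in 4 genetic groups, >=1000 SNPs with MAF
    structure, an additive + dominance architecture, and a fully
    homozygous tester.
    """

    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES
    group_names: tuple[str, ...] = DEFAULT_GROUP_NAMES
    n_commercial: int = 56  # non-testcross hybrids (two segregating parents)
    n_snps: int = 2000
    divergence: float = 0.15  # Balding-Nichols F between groups
    tester_het_fraction: float = 0.0  # fraction of loci where the tester is Aa
    sigma_a2: float = 0.6
    sigma_d2: float = 0.1
    sigma_e2: float = 0.3
    trait_mean: float = 0.0
    n_environments: int = 1
    env_genetic_correlation: float = 0.8
    trial_rows: int = 12
    trial_cols: int = 21
    spatial_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 10:
            raise ValueError("n_snps must be >= 10")
        if not any(n >= 2 for n in self.group_sizes):
            raise ValueError("at least one group needs >= 2 lines")
        if min(self.group_sizes) <= 0:
            raise ValueError("group sizes must be positive")
        for v, name in (
            (self.sigma_a2, "sigma_a2"),
            (self.sigma_d2, "sigma_d2"),
            (self.sigma_e2, "sigma_e2"),
        ):
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not -1.0 <= self.env_genetic_correlation <= 1.0:
            raise ValueError("env_genetic_correlation must be in [-1, 1]")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must be in [0, 1)")
        if not 0.0 <= self.tester_het_fraction <= 1.0:
            raise ValueError("tester_het_fraction must be in [0, 1]")
        if not 0.0 <= self.spatial_fraction <= 1.0:
            raise ValueError("spatial_fraction must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth behind one simulated trait."""

    additive_effects: np.ndarray
    dominance_effects: np.ndarray
    genetic_values: np.ndarray  # N x n_environments
    additive_values: np.ndarray  # N x n_environments
    dominance_values: np.ndarray  # N x n_environments
    sigma_a2: float
    sigma_d2: float
    sigma_e2: float
    env_genetic_correlation: float
    realized_h2: float = field(init=False)

    def __post_init__(self) -> None:
        var_g = float(np.var(self.genetic_values[:, 0]))
        var_e = self.sigma_e2
        self.realized_h2 = var_g / (var_g + var_e) if (var_g + var_e) > 0 else 0.0


def simulate_panel_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Hybrid genotypes with Balding-Nichols group structure.

    Two panel components are generated. Testcross hybrids cross a common
    tester to fully inbred lines from the structured groups: the tester
    is homozygous except at a random ``tester_het_fraction`` of loci, so
    at tester-homozygous loci a testcross hybrid shows only two genotype
    classes. ``n_commercial`` additional hybrids (group "commercial",
    emulating a historical series of commercial material) have two
    independently drawn parents and segregate in all three classes, which
    is what makes dominance relationships estimable on the pooled panel.
    Codes count the non-reference allele (0 = reference homozygote).
    """
    rng = np.random.default_rng(config.seed)
    L = config.n_snps
    # ancestral frequencies with MAF structure (U-shaped is typical for arrays
    # after ascertainment; keep away from fixation)
    p0 = rng.uniform(0.05, 0.95, size=L)
    f = config.divergence
    group_freqs = []
    for _ in config.group_sizes:
        if f > 0:
            a = p0 * (1.0 - f) / f
            b = (1.0 - p0) * (1.0 - f) / f
            group_freqs.append(rng.beta(a, b))
        else:
            group_freqs.append(p0.copy())
    # tester alleles: one haplotype; heterozygous at a chosen subset of loci
    tester_primary = (rng.random(L) < p0).astype(np.int8)
    het_loci = rng.random(L) < config.tester_het_fraction
    groups = []
    rows = []
    ids = []
    n = 0
    for g_idx, (size, name) in enumerate(zip(config.group_sizes, config.group_names)):
        pg = group_freqs[g_idx]
        for _ in range(size):
            line_allele = (rng.random(L) < pg).astype(np.int8)
            tester_allele = tester_primary.copy()
            if het_loci.any():
                flip = het_loci & (rng.random(L) < 0.5)
                tester_allele = np.where(flip, 1 - tester_allele, tester_allele)
            rows.append(line_allele + tester_allele)
            ids.append(f"{name[:3].upper()}{n:04d}")
            groups.append(name)
            n += 1
    # commercial hybrids: both parents segregate (mixture across group freqs)
    for c in range(config.n_commercial):
        pg = group_freqs[int(rng.integers(len(group_freqs)))]
        ph = group_freqs[int(rng.integers(len(group_freqs)))]
        parent1 = (rng.random(L) < pg).astype(np.int8)
        parent2 = (rng.random(L) < ph).astype(np.int8)
        rows.append(parent1 + parent2)
        ids.append(f"COM{n:04d}")
        groups.append("commercial")
        n += 1
    codes = np.vstack(rows)
    return GenotypeMatrix(codes, ids, [f"snp{j:05d}" for j in range(L)], np.array(groups))


def simulate_trait(
    genotypes: GenotypeMatrix, config: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Phenotypes from an additive + dominance architecture with known truth.

    Per-SNP effects are drawn i.i.d. normal and the resulting genetic-value
    vectors are rescaled so the realized (sample) additive and dominance
    variances equal the configured targets exactly; the residual is drawn
    at sigma_e2 without rescaling. Multi-environment values share a common
    component so that the between-environment genetic correlation equals
    ``env_genetic_correlation``.

    Returns a long observation table (hybrid, environment, value) and the truth.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = genotypes.n_hybrids
    h_a = additive_coding(genotypes)
    h_d, _ = dominance_coding(genotypes)
    n_env = config.n_environments
    rho = config.env_genetic_correlation

    def draw_values(h: np.ndarray, target_var: float) -> tuple[np.ndarray, np.ndarray]:
        k = h.shape[1]
        common = rng.standard_normal(k)
        vals = np.empty((n, n_env))
        effects = np.empty((k, n_env))
        for e in range(n_env):
            specific = rng.standard_normal(k)
            eff = np.sqrt(max(rho, 0.0)) * common + np.sqrt(1.0 - max(rho, 0.0)) * specific
            u = h @ eff
            sd = u.std()
            scale = np.sqrt(target_var) / sd if sd > 0 and target_var > 0 else 0.0
            vals[:, e] = u * scale
            effects[:, e] = eff * scale
        return vals, effects

    u_a, eff_a = draw_values(h_a, config.sigma_a2)
    u_d, eff_d = draw_values(h_d, config.sigma_d2)
    g_vals = u_a + u_d
    resid = rng.normal(0.0, np.sqrt(config.sigma_e2), size=(n, n_env))
    y = config.trait_mean + g_vals + resid
    obs = pd.DataFrame(
        {
            "hybrid": np.repeat(genotypes.hybrid_ids, n_env),
            "environment": np.tile([f"env{e}" for e in range(n_env)], n),
            "value": y.reshape(-1),
        }
    )
    truth = SimTruth(
        additive_effects=eff_a[:, 0],
        dominance_effects=eff_d[:, 0],
        genetic_values=g_vals,
        additive_values=u_a,
        dominance_values=u_d,
        sigma_a2=config.sigma_a2,
        sigma_d2=config.sigma_d2,
        sigma_e2=config.sigma_e2,
        env_genetic_correlation=rho,
    )
    return obs, truth


_PROFILE_PARAMS = {
    # (T_min, T_max, RH_day, RH_night, ppfd_max)
    "constant20": (20.0, 20.0, 70.0, 70.0, 500.0),
    "mild": (14.0, 24.0, 60.0, 85.0, 1200.0),
    "hot_dry": (20.0, 36.0, 30.0, 60.0, 1800.0),
    "cool": (8.0, 18.0, 70.0, 92.0, 900.0),
}

NIGHT_HOURS = frozenset(range(0, 6)) | frozenset(range(20, 24))


def saturation_vapor_pressure(temp_c: np.ndarray | float) -> np.ndarray | float:
    """Tetens saturation vapor pressure (kPa) at air temperature (deg C)."""
    t = np.asarray(temp_c, dtype=float)
    out = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    return out if out.ndim else float(out)


def vpd_from_rh(temp_c, rh_percent):
    """Vapor pressure deficit (kPa) from temperature and relative humidity."""
    return saturation_vapor_pressure(temp_c) * (1.0 - np.asarray(rh_percent) / 100.0)


def simulate_env_series(
    days: int,
    profile: str = "mild",
    seed: int = 0,
    irrigation_interval_days: int = 7,
    psi_wet: float = -0.05,
    psi_dry_rate: float = 0.04,
) -> pd.DataFrame:
    """Hourly environment series for one experiment.

    Columns: timestamp (hour index), temperature_C, rh_percent, vpd_kPa,
    ppfd (umol m-2 s-1, 0 at night), soil_water_potential_MPa (reset to
    ``psi_wet`` at each irrigation event, drying by ``psi_dry_rate`` MPa/day
    in between). The "constant20" profile is exactly constant (noise-free).
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if profile not in _PROFILE_PARAMS:
        raise ValueError(
            f"unknown profile {profile!r}; valid profiles: {sorted(_PROFILE_PARAMS)}"
        )
    rng = np.random.default_rng(seed)
    t_min, t_max, rh_day, rh_night, ppfd_max = _PROFILE_PARAMS[profile]
    hours = np.arange(days * 24)
    hod = hours % 24
    # diurnal temperature: min at 05:00, max at 14:00 via cosine
    phase = np.cos(2.0 * np.pi * (hod - 14.0) / 24.0)
    temp = (t_min + t_max) / 2.0 + (t_max - t_min) / 2.0 * phase
    night = np.isin(hod, list(NIGHT_HOURS))
    rh = np.where(night, rh_night, rh_day).astype(float)
    if profile != "constant20":
        temp = temp + rng.normal(0.0, 0.3, size=temp.shape)
        rh = np.clip(rh + rng.normal(0.0, 2.0, size=rh.shape), 5.0, 100.0)
    # light: half-sine over the day window
    ppfd = np.where(
        night, 0.0, ppfd_max * np.sin(np.pi * (hod - 6.0) / 14.0).clip(min=0.0)
    )
    vpd = np.maximum(vpd_from_rh(temp, rh), 0.0)
    day_idx = hours / 24.0
    since_irrigation = day_idx % irrigation_interval_days
    psi = psi_wet - psi_dry_rate * since_irrigation
    return pd.DataFrame(
        {
            "timestamp": hours,
            "temperature_C": temp,
            "rh_percent": rh,
            "vpd_kPa": vpd,
            "ppfd": ppfd,
            "soil_water_potential_MPa": psi,
        }
    )


def simulate_field_trial(
    genotype_values: np.ndarray,
    genotype_ids: list[str] | None = None,
    n_rep: int = 3,
    rows: int = 12,
    cols: int = 21,
    spatial_fraction: float = 0.3,
    residual_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Alpha-lattice-like plot table with row/column effects and a smooth surface.

    plot value = genotype value + row effect + column effect + smooth 2-D
    surface + residual. The non-genetic variance is partitioned so the
    spatial terms (rows + columns + surface) carry ``spatial_fraction`` of
    it and the i.i.d. residual the rest; ``residual_sd``^2 is the total
    non-genetic variance.
    """
    genotype_values = np.asarray(genotype_values, dtype=float)
    n_geno = genotype_values.size
    if genotype_ids is None:
        genotype_ids = [f"H{i:04d}" for i in range(n_geno)]
    n_plots = rows * cols
    if n_plots < n_geno * n_rep:
        raise ValueError(
            f"layout {rows}x{cols} too small for {n_geno} genotypes x {n_rep} reps"
        )
    rng = np.random.default_rng(seed)
    total_var = residual_sd**2
    sp_var = spatial_fraction * total_var
    res_var = total_var - sp_var
    row_eff = rng.normal(0.0, 1.0, rows)
    col_eff = rng.normal(0.0, 1.0, cols)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    u, v = rr / max(rows - 1, 1), cc / max(cols - 1, 1)
    surface = (
        rng.normal() * np.cos(np.pi * u)
        + rng.normal() * np.cos(np.pi * v)
        + rng.normal() * np.cos(np.pi * u) * np.cos(np.pi * v)
        + rng.normal() * (u - 0.5) * (v - 0.5)
    )
    spatial = row_eff[rr] + col_eff[cc] + surface
    if sp_var > 0 and spatial.std() > 0:
        spatial = spatial / spatial.std() * np.sqrt(sp_var)
    else:
        spatial = np.zeros_like(spatial)
    # replicate blocks laid out in consecutive plot runs, genotypes shuffled within
    plot_geno = np.full(n_plots, -1, dtype=int)
    pos = 0
    for _ in range(n_rep):
        order = rng.permutation(n_geno)
        plot_geno[pos : pos + n_geno] = order
        pos += n_geno
    filler = rng.integers(0, n_geno, size=n_plots - pos)  # border plots, unreplicated
    plot_geno[pos:] = filler
    rep_index = np.zeros(n_plots, dtype=int)
    rep_index[: n_rep * n_geno] = np.repeat(np.arange(1, n_rep + 1), n_geno)
    resid = rng.normal(0.0, np.sqrt(res_var), n_plots)
    flat_rows, flat_cols = rr.reshape(-1), cc.reshape(-1)
    value = (
        genotype_values[plot_geno]
        + spatial.reshape(-1)
        + resid
    )
    df = pd.DataFrame(
        {
            "genotype": [genotype_ids[i] for i in plot_geno],
            "replicate": rep_index,
            "row": flat_rows,
            "column": flat_cols,
            "value": value,
            "true_spatial": spatial.reshape(-1),
        }
    )
    return df[df["replicate"] > 0].reset_index(drop=True)


def simulate_growth_series(
    lar: float,
    ler_max: float,
    final_leaf_number: int,
    env: pd.DataFrame,
    noise_sd: float = 0.0,
    area_noise_sd: float = 0.0,
    seed: int = 0,
    observation_interval_days: int = 7,
    area_observation_interval_days: int = 1,
    logistic_midpoint: float = 34.0,
    area_saturation_scale: float = 18.0,
    clock=None,
) -> pd.DataFrame:
    """Longitudinal leaf counts and leaf-area observations for one plant.

    Leaf count at thermal time tt is min(final_leaf_number, floor(lar * tt))
    plus optional Gaussian noise on observation days (weekly by default).
    Leaf area (cm^2) follows a logistic curve in thermal time whose maximum
    slope equals ``ler_max``; daily observations by default.
    """
    if lar <= 0 or ler_max <= 0:
        raise ValueError("lar and ler_max must be > 0")
    if noise_sd < 0 or area_noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    from .phenomics import ThermalClock, thermal_time

    clock = clock or ThermalClock()
    rng = np.random.default_rng(seed)
    tt = thermal_time(env, clock)  # cumulative d_20C per hour
    n_days = len(env) // 24
    day_tt = tt[np.minimum(np.arange(1, n_days + 1) * 24 - 1, len(tt) - 1)]
    # logistic area curve: A(t) = Amax / (1 + exp(-k (t - t0))), max slope Amax*k/4;
    # larger area_saturation_scale flattens the curve toward linear growth
    a_max = ler_max * area_saturation_scale
    k = 4.0 * ler_max / a_max
    records = []
    for d in range(n_days):
        t = day_tt[d]
        if d % observation_interval_days == 0:
            count = min(final_leaf_number, np.floor(lar * t))
            if noise_sd > 0:
                count = max(0.0, count + rng.normal(0.0, noise_sd))
            records.append((d, t, "leaf_count", float(count)))
        if d % area_observation_interval_days == 0:
            area = a_max / (1.0 + np.exp(-k * (t - logistic_midpoint)))
            if area_noise_sd > 0:
                area = max(0.0, area + rng.normal(0.0, area_noise_sd))
            records.append((d, t, "leaf_area", float(area)))
    return pd.DataFrame(records, columns=["day", "thermal_time", "variable", "value"])
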