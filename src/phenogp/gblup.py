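"""Bayesian GBLUP with additive and dominance effects (GBLUP-AD).

Model: y = mu 1 + Z_a a + Z_d d (+ X beta) + eps, with
a ~ N(0, G_A sigma_a^2), d ~ N(0, G_D sigma_d^2), eps ~ N(0, I sigma_e^2)
and optional fixed marker effects beta (flat prior).

Sampling is single-site Gibbs in the eigenbasis of each relationship
matrix: writing G = U S U' and a = U S^(1/2) alpha, the prior on alpha is
i.i.d. N(0, sigma_a^2) and its full-conditional precision is diagonal,
so each effect vector is drawn jointly in O(N^2) per sweep. Variance
components carry scaled-inverse-chi-square priors; missing phenotypes
are data-augmented, which is how unobserved hybrids are predicted
(masked responses, joint fit).

The bivariate variant fits two traits jointly with 2x2 additive,
dominance and residual covariance matrices under inverse-Wishart priors
and reports the additive genetic correlation
r_g = V_a[0,1] / sqrt(V_a[0,0] V_a[1,1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genomics import RelationshipPair

EIG_TOL = 1e-8


class NonPSDError(ValueError):
    """Relationship matrix is not positive semi-definite within tolerance."""


@dataclass
class MCMCConfig:
    """Gibbs-sampler settings.

    The "published" profile (60,000 iterations, 10,000 burn-in, thinning 5)
    matches the published sampler settings; "test" (6,000/1,000/5) is the
    desk-scale default.
    """

    iterations: int = 6000
    burn_in: int = 1000
    thinning: int = 5
    seed: int = 0
    prior_df: float = 5.0
    prior_r2: float = 0.5  # prior fraction of var(y) assigned to genetics

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @classmethod
    def profile(cls, name: str, seed: int = 0) -> "MCMCConfig":
        if name == "published":
            return cls(iterations=60000, burn_in=10000, thinning=5, seed=seed)
        if name == "test":
            return cls(iterations=6000, burn_in=1000, thinning=5, seed=seed)
        raise ValueError(f"unknown MCMC profile {name!r}; use 'published' or 'test'")


@dataclass
class GBLUPFit:
    """Posterior summaries of one GBLUP-AD fit."""

    mu: float
    additive: np.ndarray
    dominance: np.ndarray | None
    beta: np.ndarray | None
    sigma_a2: float
    sigma_d2: float | None
    sigma_e2: float
    sigma_a2_sd: float
    sigma_d2_sd: float | None
    sigma_e2_sd: float
    predicted: np.ndarray
    n_samples: int
    observed_mask: np.ndarray

    @property
    def genetic_values(self) -> np.ndarray:
        g = self.additive.copy()
        if self.dominance is not None:
            g = g + self.dominance
        return g


def _eig_factor(g: np.ndarray, label: str) -> tuple[np.ndarray, np.ndarray]:
    """W = U sqrt(S) over the positive spectrum; errors on indefinite input."""
    g = np.asarray(g, dtype=float)
    s, u = np.linalg.eigh((g + g.T) / 2.0)
    if s.min() < -1e-6 * max(abs(s.max()), 1.0):
        raise NonPSDError(
            f"{label} has eigenvalue {s.min():.3e} < 0; add a small diagonal jitter"
        )
    keep = s > EIG_TOL * max(s.max(), 1.0)
    return u[:, keep] * np.sqrt(s[keep]), s[keep]


def _scaled_inv_chi2(rng, df: float, scale: float) -> float:
    return df * scale / rng.chisquare(df)


def fit_gblup_ad(
    y: np.ndarray,
    rel: RelationshipPair,
    mcmc: MCMCConfig | None = None,
    fixed_markers: np.ndarray | None = None,
    dominance: bool = True,
    fix_variances: tuple[float, float] | tuple[float, float, float] | None = None,
) -> GBLUPFit:
    """Gibbs sampler for the additive + dominance GBLUP.

    ``y`` may contain NaN for unobserved hybrids; these are treated as
    missing at random, augmented during sampling and predicted jointly.
    Returns posterior means (and sds for variance components) over the
    thinned post-burn-in samples.

    ``fix_variances`` holds (sigma_a2, sigma_e2) or (sigma_a2, sigma_e2,
    sigma_d2) to run at known variance components (e.g. to compare the
    sampler with the mixed-model-equation solution at a known ratio).
    """
    mcmc = mcmc or MCMCConfig()
    y = np.asarray(y, dtype=float)
    n = y.size
    if rel.g_add.shape != (n, n):
        raise ValueError("relationship matrix dimensions do not match y")
    observed = ~np.isnan(y)
    if not observed.any():
        raise ValueError("no observed phenotypes")
    rng = np.random.default_rng(mcmc.seed)

    w_a, s_a = _eig_factor(rel.g_add, "G_A")
    use_dom = dominance and rel.g_dom is not None
    if use_dom:
        w_d, s_d = _eig_factor(rel.g_dom, "G_D")

    x = None
    if fixed_markers is not None:
        x = np.column_stack([np.asarray(fixed_markers, dtype=float)])
        xtx_chol = np.linalg.cholesky(x.T @ x)

    var_y = float(np.var(y[observed]))
    var_y = var_y if var_y > 0 else 1e-8
    df0 = mcmc.prior_df
    n_gen_terms = 2 if use_dom else 1
    # prior modes: prior_r2 * var(y) split across genetic terms, rest residual
    mode_g = mcmc.prior_r2 * var_y / n_gen_terms
    mode_e = (1.0 - mcmc.prior_r2) * var_y
    s0_g = mode_g * (df0 + 2.0) / df0
    s0_e = mode_e * (df0 + 2.0) / df0

    # state
    y_aug = np.where(observed, y, float(np.nanmean(y)))
    mu = float(np.mean(y_aug))
    alpha = np.zeros(w_a.shape[1])
    a_vec = np.zeros(n)
    delta = np.zeros(w_d.shape[1]) if use_dom else None
    d_vec = np.zeros(n)
    beta = np.zeros(x.shape[1]) if x is not None else None
    xb = np.zeros(n)
    sig_a2, sig_d2, sig_e2 = mode_g, mode_g, mode_e
    if fix_variances is not None:
        sig_a2, sig_e2 = float(fix_variances[0]), float(fix_variances[1])
        sig_d2 = float(fix_variances[2]) if len(fix_variances) > 2 else sig_d2

    keep = [0.0, np.zeros(n), np.zeros(n), 0.0, 0.0, 0.0,
            np.zeros(x.shape[1]) if x is not None else None]
    sums_sq = [0.0, 0.0, 0.0]
    samples_var = []
    n_kept = 0

    for it in range(mcmc.iterations):
        # additive block (joint draw in the eigenbasis)
        r = y_aug - mu - d_vec - xb
        b = w_a.T @ r
        prec = s_a / sig_e2 + 1.0 / sig_a2
        mean = b / sig_e2 / prec
        alpha = mean + rng.standard_normal(alpha.size) / np.sqrt(prec)
        a_vec = w_a @ alpha
        if use_dom:
            r = y_aug - mu - a_vec - xb
            b = w_d.T @ r
            prec = s_d / sig_e2 + 1.0 / sig_d2
            mean = b / sig_e2 / prec
            delta = mean + rng.standard_normal(delta.size) / np.sqrt(prec)
            d_vec = w_d @ delta
        if x is not None:
            r = y_aug - mu - a_vec - d_vec
            rhs = x.T @ r
            bhat = np.linalg.solve(xtx_chol @ xtx_chol.T, rhs)
            z = rng.standard_normal(beta.size)
            beta = bhat + np.sqrt(sig_e2) * np.linalg.solve(xtx_chol.T, z)
            xb = x @ beta
        resid_nomu = y_aug - a_vec - d_vec - xb
        mu = float(rng.normal(resid_nomu.mean(), np.sqrt(sig_e2 / n)))
        resid = resid_nomu - mu
        if fix_variances is None:
            # variance components (scaled-inverse-chi-square full conditionals)
            sig_a2 = _scaled_inv_chi2(
                rng, df0 + alpha.size, (df0 * s0_g + alpha @ alpha) / (df0 + alpha.size)
            )
            if use_dom:
                sig_d2 = _scaled_inv_chi2(
                    rng, df0 + delta.size, (df0 * s0_g + delta @ delta) / (df0 + delta.size)
                )
            sig_e2 = _scaled_inv_chi2(
                rng, df0 + n, (df0 * s0_e + resid @ resid) / (df0 + n)
            )
        if not np.isfinite(sig_e2) or sig_e2 > 1e12 * var_y:
            raise FloatingPointError(
                f"divergent chain at iteration {it}: sigma_e2={sig_e2:.3e}"
            )
        # data augmentation for masked phenotypes
        if not observed.all():
            miss = ~observed
            y_aug[miss] = (
                mu + a_vec[miss] + d_vec[miss] + xb[miss]
                + rng.normal(0.0, np.sqrt(sig_e2), miss.sum())
            )
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thinning == 0:
            n_kept += 1
            keep[0] += mu
            keep[1] += a_vec
            keep[2] += d_vec
            keep[3] += sig_a2
            keep[4] += sig_d2
            keep[5] += sig_e2
            if x is not None:
                keep[6] += beta
            sums_sq[0] += sig_a2**2
            sums_sq[1] += sig_d2**2
            sums_sq[2] += sig_e2**2

    mu_m = keep[0] / n_kept
    a_m = keep[1] / n_kept
    d_m = keep[2] / n_kept
    sa_m, sd_m, se_m = keep[3] / n_kept, keep[4] / n_kept, keep[5] / n_kept
    beta_m = keep[6] / n_kept if x is not None else None

    def post_sd(sum_sq, mean):
        return float(np.sqrt(max(sum_sq / n_kept - mean**2, 0.0)))

    predicted = mu_m + a_m + d_m + (x @ beta_m if x is not None else 0.0)
    return GBLUPFit(
        mu=float(mu_m),
        additive=a_m,
        dominance=d_m if use_dom else None,
        beta=beta_m,
        sigma_a2=float(sa_m),
        sigma_d2=float(sd_m) if use_dom else None,
        sigma_e2=float(se_m),
        sigma_a2_sd=post_sd(sums_sq[0], sa_m),
        sigma_d2_sd=post_sd(sums_sq[1], sd_m) if use_dom else None,
        sigma_e2_sd=post_sd(sums_sq[2], se_m),
        predicted=np.asarray(predicted),
        n_samples=n_kept,
        observed_mask=observed,
    )


def predict_masked(fit: GBLUPFit) -> np.ndarray:
    """Predicted values for the hybrids whose phenotypes were masked."""
    masked = ~fit.observed_mask
    if not masked.any():
        raise ValueError("no masked hybrids in this fit")
    return fit.predicted[masked]


def genomic_heritability(
    sigma_a2: float,
    sigma_d2: float | None = None,
    sigma_e2: float | None = None,
    mode: str = "total",
) -> float:
    """Genomic heritability from variance components.

    mode "total" (default): (sigma_a2 + sigma_d2) / (sigma_a2 + sigma_d2 +
    sigma_e2) — the form that reconstructs published per-trait values;
    mode "additive": sigma_a2 / (sigma_a2 + sigma_d2 + sigma_e2).
    """
    sd = sigma_d2 or 0.0
    if sigma_e2 is None:
        raise ValueError("sigma_e2 is required")
    total = sigma_a2 + sd + sigma_e2
    if total <= 0:
        raise ValueError("all variance components are zero; heritability undefined")
    if mode == "total":
        return (sigma_a2 + sd) / total
    if mode == "additive":
        return sigma_a2 / total
    raise ValueError("mode must be 'total' or 'additive'")


def heritability_of_fit(fit: GBLUPFit, mode: str = "total") -> float:
    return genomic_heritability(fit.sigma_a2, fit.sigma_d2, fit.sigma_e2, mode)


@dataclass
class PCBLUPFit:
    """Linear fit of a trait on leading PCoA coordinates."""

    intercept: float
    coefficients: np.ndarray
    predicted: np.ndarray
    observed_mask: np.ndarray


def fit_pc_blup(
    y: np.ndarray, coords: np.ndarray, n_axes: int = 5, ridge: float = 0.0
) -> PCBLUPFit:
    """Population-structure-only predictor: trait on the first PCoA axes.

    Fits on observed entries (NaN = masked) by least squares (optionally
    ridge-penalized) and predicts all hybrids from their coordinates.
    Uses fewer axes with a warning if not enough are available.
    """
    import warnings as _w

    y = np.asarray(y, dtype=float)
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[1] < n_axes:
        _w.warn(
            f"only {coords.shape[1]} axes available; requested {n_axes}", stacklevel=2
        )
        n_axes = coords.shape[1]
    c = coords[:, :n_axes]
    observed = ~np.isnan(y)
    x = np.column_stack([np.ones(observed.sum()), c[observed]])
    a = x.T @ x + ridge * np.diag(np.r_[0.0, np.ones(n_axes)])
    coef = np.linalg.solve(a, x.T @ y[observed])
    predicted = coef[0] + c @ coef[1:]
    return PCBLUPFit(float(coef[0]), coef[1:], predicted, observed)


@dataclass
class BivariateFit:
    """Posterior summaries of the two-trait GBLUP-AD."""

    v_add: np.ndarray  # 2x2 additive covariance
    v_dom: np.ndarray  # 2x2 dominance covariance
    v_resid: np.ndarray  # 2x2 residual covariance
    mu: np.ndarray
    n_samples: int

    @property
    def genetic_correlation(self) -> float:
        va = self.v_add
        return float(va[0, 1] / np.sqrt(va[0, 0] * va[1, 1]))


def fit_bivariate(
    y1: np.ndarray,
    y2: np.ndarray,
    rel: RelationshipPair,
    mcmc: MCMCConfig | None = None,
    min_shared: int = 15,
) -> BivariateFit:
    """Two-trait GBLUP-AD by Gibbs sampling with inverse-Wishart priors.

    ``y1`` and ``y2`` are trait vectors over the same hybrids (the panel
    behind ``rel``); hybrids missing either trait are dropped, and at
    least ``min_shared`` shared hybrids are required. The additive
    genetic correlation between the two traits (e.g. the same trait in
    two experiments) is derived from the posterior mean of V_a.
    """
    mcmc = mcmc or MCMCConfig()
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    shared = ~np.isnan(y1) & ~np.isnan(y2)
    n_shared = int(shared.sum())
    if n_shared == 0:
        raise ValueError("no hybrids shared between the two traits")
    if n_shared < min_shared:
        raise ValueError(f"only {n_shared} shared hybrids; need >= {min_shared}")
    idx = np.where(shared)[0]
    y = np.column_stack([y1[idx], y2[idx]])
    ga = rel.g_add[np.ix_(idx, idx)]
    gd = rel.g_dom[np.ix_(idx, idx)] if rel.g_dom is not None else None
    n = len(idx)
    rng = np.random.default_rng(mcmc.seed)

    w_a, s_a = _eig_factor(ga, "G_A")
    use_dom = gd is not None
    if use_dom:
        w_d, s_d = _eig_factor(gd, "G_D")

    nu0 = 4.0
    var_y = np.var(y, axis=0)
    var_y = np.where(var_y > 0, var_y, 1e-8)
    n_gen = 2 if use_dom else 1
    psi_g = np.diag(0.5 * var_y / n_gen) * (nu0 - 3.0)  # prior mean = psi/(nu-p-1)
    psi_e = np.diag(0.5 * var_y) * (nu0 - 3.0)

    mu = y.mean(axis=0)
    alpha = np.zeros((w_a.shape[1], 2))
    a_mat = np.zeros((n, 2))
    delta = np.zeros((w_d.shape[1], 2)) if use_dom else None
    d_mat = np.zeros((n, 2))
    v_a = np.diag(0.25 * var_y)
    v_d = np.diag(0.25 * var_y)
    v_e = np.diag(0.5 * var_y)

    sum_va = np.zeros((2, 2))
    sum_vd = np.zeros((2, 2))
    sum_ve = np.zeros((2, 2))
    sum_mu = np.zeros(2)
    n_kept = 0

    def draw_effect_fast(w, s, other, v_g):
        # with a = W alpha, W = U sqrt(S): rows alpha_j ~ N(0, v_g) give
        # a ~ N(0, G (x) v_g); rotating residuals by U' keeps I (x) R, so the
        # per-eigencomponent conditional is a 2x2 Gaussian with precision
        # s_j inv(R) + inv(v_g) and mean cov_j @ inv(R) @ (W' r)_j
        r = y - mu - other
        r = y - mu - other
        b = w.T @ r
        ve_inv = np.linalg.inv(v_e)
        vg_inv = np.linalg.inv(v_g)
        k = s.size
        # precision_j = s_j * ve_inv + vg_inv ; mean_j = cov_j @ ve_inv @ b_j
        precs = s[:, None, None] * ve_inv[None] + vg_inv[None]
        covs = np.linalg.inv(precs)
        means = np.einsum("kij,jl,kl->ki", covs, ve_inv, b)
        chols = np.linalg.cholesky(covs)
        z = rng.standard_normal((k, 2))
        return means + np.einsum("kij,kj->ki", chols, z)

    for it in range(mcmc.iterations):
        alpha = draw_effect_fast(w_a, s_a, d_mat, v_a)
        a_mat = w_a @ alpha
        if use_dom:
            delta = draw_effect_fast(w_d, s_d, a_mat, v_d)
            d_mat = w_d @ delta
        resid_nomu = y - a_mat - d_mat
        mu_mean = resid_nomu.mean(axis=0)
        mu_cov = v_e / n
        mu = mu_mean + np.linalg.cholesky(mu_cov) @ rng.standard_normal(2)
        resid = resid_nomu - mu
        v_a = stats.invwishart.rvs(
            df=nu0 + alpha.shape[0], scale=psi_g + alpha.T @ alpha, random_state=rng
        )
        if use_dom:
            v_d = stats.invwishart.rvs(
                df=nu0 + delta.shape[0], scale=psi_g + delta.T @ delta, random_state=rng
            )
        v_e = stats.invwishart.rvs(
            df=nu0 + n, scale=psi_e + resid.T @ resid, random_state=rng
        )
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thinning == 0:
            n_kept += 1
            sum_va += v_a
            sum_vd += v_d
            sum_ve += v_e
            sum_mu += mu

    return BivariateFit(
        v_add=sum_va / n_kept,
        v_dom=sum_vd / n_kept,
        v_resid=sum_ve / n_kept,
        mu=sum_mu / n_kept,
        n_samples=n_kept,
    )
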