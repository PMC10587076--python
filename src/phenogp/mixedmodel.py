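"""Dense REML machinery for small mixed models.

Model: y = X b + sum_k Z_k u_k + e with u_k ~ N(0, sigma_k^2 I) and
e ~ N(0, sigma_e^2 I). Variance ratios gamma_k = sigma_k^2 / sigma_e^2 are
estimated by minimizing the profiled REML deviance with L-BFGS-B on
log(gamma); sigma_e^2 is profiled out. Sized for trial-scale problems
(hundreds to a few thousand plots) where dense n x n algebra is cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize


@dataclass
class MixedFit:
    beta: np.ndarray
    beta_cov: np.ndarray
    u: list[np.ndarray]  # BLUPs per random block
    sigma2: list[float]  # variance components per random block
    sigma2_e: float
    gamma: np.ndarray
    reml_deviance: float


def _reml_deviance(log_gamma: np.ndarray, y, x, z_list):
    n, p = x.shape
    gamma = np.exp(log_gamma)
    v = np.eye(n)
    for g, z in zip(gamma, z_list):
        v += g * (z @ z.T)
    try:
        c = linalg.cholesky(v, lower=True)
    except linalg.LinAlgError:
        return 1e10
    logdet_v = 2.0 * np.log(np.diag(c)).sum()
    vi_y = linalg.cho_solve((c, True), y)
    vi_x = linalg.cho_solve((c, True), x)
    xtvx = x.T @ vi_x
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return 1e10
    beta = np.linalg.solve(xtvx, x.T @ vi_y)
    r = y - x @ beta
    quad = float(r @ (vi_y - vi_x @ beta))
    if quad <= 0:
        return 1e10
    s2 = quad / (n - p)
    return (n - p) * np.log(s2) + logdet_v + logdet_x + (n - p)


def fit_reml(
    y: np.ndarray,
    x: np.ndarray,
    z_list: list[np.ndarray],
    start_log_gamma: float = -1.0,
) -> MixedFit:
    """REML fit; returns GLS fixed effects, BLUPs and variance components."""
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, p = x.shape
    if n <= p:
        raise ValueError("more fixed-effect columns than observations")
    k = len(z_list)
    if k:
        res = optimize.minimize(
            _reml_deviance,
            np.full(k, start_log_gamma),
            args=(y, x, z_list),
            method="L-BFGS-B",
            bounds=[(-12.0, 8.0)] * k,
        )
        gamma = np.exp(res.x)
        dev = float(res.fun)
    else:
        gamma = np.empty(0)
        dev = float(_reml_deviance(np.empty(0), y, x, z_list))
    v = np.eye(n)
    for g, z in zip(gamma, z_list):
        v += g * (z @ z.T)
    c = linalg.cholesky(v, lower=True)
    vi_y = linalg.cho_solve((c, True), y)
    vi_x = linalg.cho_solve((c, True), x)
    xtvx = x.T @ vi_x
    beta = np.linalg.solve(xtvx, x.T @ vi_y)
    r = y - x @ beta
    vi_r = vi_y - vi_x @ beta
    s2e = float(r @ vi_r) / (n - p)
    u = [g * (z.T @ vi_r) for g, z in zip(gamma, z_list)]
    return MixedFit(
        beta=beta,
        beta_cov=np.linalg.inv(xtvx) * s2e,
        u=u,
        sigma2=[float(g * s2e) for g in gamma],
        sigma2_e=s2e,
        gamma=gamma,
        reml_deviance=dev,
    )


def bspline_basis(x: np.ndarray, n_basis: int, degree: int = 3) -> np.ndarray:
    """Cubic B-spline basis over the range of x with equally spaced knots."""
    from scipy.interpolate import BSpline

    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return np.ones((x.size, 1))
    n_inner = max(n_basis - degree - 1, 0)
    inner = np.linspace(lo, hi, n_inner + 2)[1:-1]
    knots = np.r_[[lo] * (degree + 1), inner, [hi] * (degree + 1)]
    n_funcs = len(knots) - degree - 1
    basis = np.empty((x.size, n_funcs))
    for i in range(n_funcs):
        coef = np.zeros(n_funcs)
        coef[i] = 1.0
        basis[:, i] = BSpline(knots, coef, degree, extrapolate=False)(x)
    return np.nan_to_num(basis)


def tensor_surface_basis(
    row: np.ndarray, col: np.ndarray, n_row_basis: int = 6, n_col_basis: int = 6
) -> np.ndarray:
    """Tensor product of row and column B-spline bases (smooth 2-D surface)."""
    br = bspline_basis(row, n_row_basis)
    bc = bspline_basis(col, n_col_basis)
    return (br[:, :, None] * bc[:, None, :]).reshape(len(row), -1)
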