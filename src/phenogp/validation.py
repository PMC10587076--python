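"""Stratified cross-validation, external validation and prediction metrics.

The evaluation scheme is CV1: whole hybrids are left out, so a masked
hybrid is never seen in any environment. Folds are drawn proportionally
to strata (genetic groups for a diversity panel, release-period bins for
a historical panel), metrics are computed within each fold and then
averaged across folds and iterations.

Metrics: Pearson r and Spearman rho between observed BLUEs and predicted
values with Bonett-Wright standard errors; selection accuracy
Acc = r / sqrt(h_g^2); RMSE and bias with their coefficient-of-variation
forms (percent of mean observed value); quartile concordance; and the
indirect-selection pair iAcc = r_g * sqrt(h2_source),
Eff = iAcc / sqrt(h2_target).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gblup import MCMCConfig, fit_gblup_ad, fit_pc_blup
from .genomics import RelationshipPair

RELEASE_PERIOD_BINS = ((-np.inf, 1980), (1980, 2000), (2000, np.inf))


def release_period_strata(years: np.ndarray) -> np.ndarray:
    """Bin release years into the <1980 / 1980-2000 / >2000 periods."""
    years = np.asarray(years, dtype=float)
    labels = np.empty(years.size, dtype=object)
    labels[years < 1980] = "pre1980"
    labels[(years >= 1980) & (years <= 2000)] = "1980_2000"
    labels[years > 2000] = "post2000"
    return labels


@dataclass
class CVPlan:
    """Stratified fold assignments: (iterations x hybrids) fold indices."""

    k: int
    iterations: int
    strata: np.ndarray
    seed: int
    assignments: np.ndarray  # shape (iterations, n_hybrids), values 0..k-1

    def folds(self, iteration: int):
        for f in range(self.k):
            yield np.where(self.assignments[iteration] == f)[0]


def make_cv_plan(
    strata: np.ndarray, k: int = 5, iterations: int = 10, seed: int = 0
) -> CVPlan:
    """Random fold assignment, proportional within every stratum.

    Members of each stratum are shuffled and dealt round-robin into
    folds; the dealing position carries over between strata so overall
    fold sizes also differ by at most one. Warns when k exceeds the
    smallest stratum (proportionality then degrades to best effort).
    """
    strata = np.asarray(strata)
    if k < 2:
        raise ValueError("k must be >= 2")
    uniq, counts = np.unique(strata, return_counts=True)
    if counts.min() == 0:
        raise ValueError("empty stratum")
    if k > counts.min():
        warnings.warn(
            f"k={k} exceeds smallest stratum ({counts.min()}); "
            "proportionality degraded",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n = strata.size
    assignments = np.empty((iterations, n), dtype=int)
    for it in range(iterations):
        cursor = int(rng.integers(k))
        for s in uniq:
            idx = np.where(strata == s)[0]
            rng.shuffle(idx)
            for i in idx:
                assignments[it, i] = cursor % k
                cursor += 1
    return CVPlan(k, iterations, strata, seed, assignments)


def bonett_wright_se(r: float, n: int, kind: str = "pearson") -> float:
    """Bonett-Wright approximate SE of a correlation coefficient.

    pearson: (1 - r^2)/sqrt(n - 3); spearman adds the sqrt(1 + r^2/2)
    inflation factor.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    base = (1.0 - r**2) / np.sqrt(n - 3)
    if kind == "pearson":
        return float(base)
    if kind == "spearman":
        return float(np.sqrt(1.0 + r**2 / 2.0) * base)
    raise ValueError("kind must be 'pearson' or 'spearman'")


def accuracy(r: float, h2: float) -> float:
    """Selection accuracy Acc = r / sqrt(h2); flagged when > 1.05."""
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must be in (0, 1]")
    acc = r / np.sqrt(h2)
    if acc > 1.05:
        warnings.warn(f"accuracy {acc:.3f} > 1.05; check h2", stacklevel=2)
    return float(acc)


def error_metrics(observed: np.ndarray, predicted: np.ndarray) -> dict[str, float]:
    """RMSE, CV_RMSE (%), bias = mean(pred - obs), CV_bias (%)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size != predicted.size or observed.size < 2:
        raise ValueError("need equal-length vectors with >= 2 entries")
    mean_obs = observed.mean()
    if mean_obs == 0:
        raise ValueError("zero mean observed value: CV forms undefined")
    rmse = float(np.sqrt(np.mean((observed - predicted) ** 2)))
    bias = float(np.mean(predicted - observed))
    return {
        "rmse": rmse,
        "cv_rmse": 100.0 * rmse / abs(mean_obs),
        "bias": bias,
        "cv_bias": 100.0 * bias / abs(mean_obs),
    }


def quartile_concordance(
    x: np.ndarray, y: np.ndarray, ids: list | None = None
) -> tuple[float, float]:
    """Fraction of top- and bottom-quartile members shared between x and y.

    Quartile size is ceil(n/4); ties are broken by stable genotype-ID
    order (the input order when ids are omitted).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError("need n >= 8")
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if ids is not None and len(set(ids)) != n:
        raise ValueError("duplicated genotype ids")
    q = int(np.ceil(n / 4))
    # stable sort keeps input/ID order among ties
    top_x = set(np.argsort(-x, kind="stable")[:q])
    top_y = set(np.argsort(-y, kind="stable")[:q])
    bot_x = set(np.argsort(x, kind="stable")[:q])
    bot_y = set(np.argsort(y, kind="stable")[:q])
    return len(top_x & top_y) / q, len(bot_x & bot_y) / q


def indirect_selection(rg: float, h2_source: float, h2_target: float) -> tuple[float, float]:
    """iAcc = r_g sqrt(h2_source); Eff = iAcc / sqrt(h2_target)."""
    if not 0.0 < h2_source <= 1.0 or not 0.0 < h2_target <= 1.0:
        raise ValueError("heritabilities must be in (0, 1]")
    iacc = rg * np.sqrt(h2_source)
    return float(iacc), float(iacc / np.sqrt(h2_target))


@dataclass
class MetricReport:
    """Across-fold summary of prediction quality."""

    per_fold: pd.DataFrame
    h2: float

    def _mean(self, col: str) -> float:
        return float(self.per_fold[col].mean())

    @property
    def r(self) -> float:
        return self._mean("r")

    @property
    def rho(self) -> float:
        return self._mean("rho")

    @property
    def acc(self) -> float:
        return self._mean("acc")

    @property
    def rmse(self) -> float:
        return self._mean("rmse")

    @property
    def cv_rmse(self) -> float:
        return self._mean("cv_rmse")

    @property
    def bias(self) -> float:
        return self._mean("bias")

    @property
    def cv_bias(self) -> float:
        return self._mean("cv_bias")

    @property
    def n(self) -> int:
        return int(self.per_fold["n"].sum())

    def summary(self) -> dict[str, float]:
        n_mean = float(self.per_fold["n"].mean())
        return {
            "r": self.r,
            "r_se": bonett_wright_se(self.r, max(int(n_mean), 4)),
            "rho": self.rho,
            "rho_se": bonett_wright_se(self.rho, max(int(n_mean), 4), "spearman"),
            "acc": self.acc,
            "rmse": self.rmse,
            "cv_rmse": self.cv_rmse,
            "bias": self.bias,
            "cv_bias": self.cv_bias,
            "n_folds": int(len(self.per_fold)),
            "n": self.n,
            "h2": self.h2,
        }


def _fold_metrics(obs, pred, h2, n_min=3):
    r = float(np.corrcoef(obs, pred)[0, 1])
    rho = float(stats.spearmanr(obs, pred).statistic)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        acc = accuracy(r, h2)
    out = {"r": r, "rho": rho, "acc": acc, "n": obs.size}
    out.update(error_metrics(obs, pred))
    return out


def run_cv(
    y: np.ndarray,
    rel: RelationshipPair | None,
    plan: CVPlan,
    h2: float,
    mcmc: MCMCConfig | None = None,
    model: str = "gblup_ad",
    coords: np.ndarray | None = None,
    predictor=None,
) -> MetricReport:
    """Cross-validated prediction quality under a stratified CV1 plan.

    For each fold: fit on the training four fifths (masked responses for
    the fold), predict the fold, compute metrics within the fold; the
    report averages across all folds and iterations. ``model`` selects
    GBLUP-AD (default) or PC-BLUP on PCoA ``coords``; a custom
    ``predictor(y_masked) -> predictions`` callable overrides both.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("CV requires complete phenotypes over the plan")
    rows = []
    for it in range(plan.iterations):
        for f, test_idx in enumerate(plan.folds(it)):
            if test_idx.size < 3:
                warnings.warn(f"fold {f} has < 3 test hybrids; skipped", stacklevel=2)
                continue
            y_masked = y.copy()
            y_masked[test_idx] = np.nan
            if predictor is not None:
                pred = np.asarray(predictor(y_masked))
            elif model == "gblup_ad":
                cfg = mcmc or MCMCConfig()
                fold_cfg = MCMCConfig(
                    cfg.iterations, cfg.burn_in, cfg.thinning,
                    seed=cfg.seed + 1000 * it + f,
                    prior_df=cfg.prior_df, prior_r2=cfg.prior_r2,
                )
                fit = fit_gblup_ad(y_masked, rel, fold_cfg)
                pred = fit.predicted
            elif model == "pc_blup":
                if coords is None:
                    raise ValueError("pc_blup requires PCoA coordinates")
                pred = fit_pc_blup(y_masked, coords).predicted
            else:
                raise ValueError(f"unknown model {model!r}")
            m = _fold_metrics(y[test_idx], pred[test_idx], h2)
            m.update({"iteration": it, "fold": f})
            rows.append(m)
    return MetricReport(pd.DataFrame(rows), h2)


def external_validation(
    y_train: np.ndarray,
    y_test: np.ndarray,
    rel: RelationshipPair,
    h2_test: float,
    mcmc: MCMCConfig | None = None,
) -> MetricReport:
    """Train on one panel union, predict a disjoint test panel.

    ``y_train`` and ``y_test`` are full-length vectors over the combined
    panel (NaN where a hybrid does not belong to that set); the sets must
    be disjoint and the relationship matrices span the union. A single
    fit with the test phenotypes masked supplies the predictions.
    """
    y_train = np.asarray(y_train, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    train_mask = ~np.isnan(y_train)
    test_mask = ~np.isnan(y_test)
    if not test_mask.any():
        raise ValueError("empty test set")
    if (train_mask & test_mask).any():
        raise ValueError("train and test hybrid sets overlap")
    fit = fit_gblup_ad(y_train, rel, mcmc)
    obs = y_test[test_mask]
    pred = fit.predicted[test_mask]
    m = _fold_metrics(obs, pred, h2_test)
    m.update({"iteration": 0, "fold": 0})
    return MetricReport(pd.DataFrame([m]), h2_test)
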