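"""Causal-effect estimators for two-sample MR summary data.

All estimators consume aligned effect pairs (gamma_j, se_gamma_j) on the
exposure and (Gamma_j, se_Gamma_j) on the outcome and estimate the causal
effect beta in Gamma_j = beta * gamma_j (+ pleiotropy).  The per-SNP
building block is the Wald ratio Gamma_j / gamma_j with first-order
standard error se_Gamma_j / |gamma_j| (exposure-side uncertainty ignored,
appropriate for strong instruments).

The classes follow the scikit-learn estimator protocol: construct with
hyper-parameters, ``fit(X)`` where ``X`` is a :class:`~mrkit.summary_io.
HarmonizedSet`, a pair DataFrame, or an array of shape (J, 4) ordered
(gamma, se_gamma, Gamma, se_Gamma); results land in trailing-underscore
attributes (``beta_``, ``se_``, ``pval_``, ...).  Module-level functions
(:func:`ivw`, :func:`egger`, :func:`weighted_median`, :func:`weighted_mode`)
are thin wrappers returning :class:`MREstimate` records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .summary_io import as_effect_arrays

__all__ = [
    "MREstimate",
    "IVWEstimator",
    "EggerEstimator",
    "WeightedMedianEstimator",
    "WeightedModeEstimator",
    "wald_ratios",
    "ivw",
    "egger",
    "weighted_median",
    "weighted_mode",
    "weighted_median_point",
    "to_odds_ratio",
    "estimates_table",
]


@dataclass(frozen=True)
class MREstimate:
    """One method's causal-effect estimate, on log-odds and odds-ratio scales."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    or_: float
    or_ci_low: float
    or_ci_high: float
    level: float = 0.95
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None


def to_odds_ratio(estimate: MREstimate, level: float = 0.95) -> MREstimate:
    """Exponentiate a log-odds estimate: OR = exp(beta), Wald CI on the log scale."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    return replace(
        estimate,
        level=level,
        ci_low=estimate.beta - z * estimate.se,
        ci_high=estimate.beta + z * estimate.se,
        or_=math.exp(estimate.beta),
        or_ci_low=math.exp(estimate.beta - z * estimate.se),
        or_ci_high=math.exp(estimate.beta + z * estimate.se),
    )


def wald_ratios(h) -> pd.DataFrame:
    """Per-SNP Wald ratios: ratio_j = Gamma_j/gamma_j, se = se_Gamma_j/|gamma_j|."""
    ids, gamma, se_gamma, Gamma, se_Gamma = as_effect_arrays(h)
    zero = np.flatnonzero(gamma == 0.0)
    if zero.size:
        raise ValueError(f"zero exposure effect for SNP(s): {list(ids[zero])}")
    return pd.DataFrame(
        {"snp_id": ids, "ratio": Gamma / gamma, "ratio_se": se_Gamma / np.abs(gamma)}
    )


def _ratio_arrays(h):
    ids, gamma, se_gamma, Gamma, se_Gamma = as_effect_arrays(h)
    if np.any(gamma == 0.0):
        bad = list(np.asarray(ids)[gamma == 0.0])
        raise ValueError(f"zero exposure effect for SNP(s): {bad}")
    ratio = Gamma / gamma
    ratio_se = se_Gamma / np.abs(gamma)
    return ids, gamma, se_gamma, Gamma, se_Gamma, ratio, ratio_se


class _MRRegressorBase(BaseEstimator):
    """Shared fit plumbing; subclasses implement ``_estimate``."""

    _min_snps = 1

    def fit(self, X, y=None):
        ids, gamma, se_gamma, Gamma, se_Gamma, ratio, ratio_se = _ratio_arrays(X)
        j = gamma.size
        if j < self._min_snps:
            raise ValueError(
                f"{type(self).__name__} requires at least {self._min_snps} SNPs, got {j}"
            )
        self.n_snps_ = int(j)
        self._estimate(gamma, se_gamma, Gamma, se_Gamma, ratio, ratio_se)
        level = getattr(self, "level", 0.95)
        z = stats.norm.ppf(0.5 + level / 2.0)
        self.ci_low_ = self.beta_ - z * self.se_
        self.ci_high_ = self.beta_ + z * self.se_
        return self

    def predict(self, gamma):
        """Predicted outcome effects beta_ * gamma (plus intercept if any)."""
        gamma = np.asarray(gamma, dtype=float)
        intercept = getattr(self, "intercept_", 0.0) or 0.0
        return intercept + self.beta_ * gamma

    def to_estimate(self, level: float = 0.95) -> MREstimate:
        est = MREstimate(
            method=self.method,
            beta=float(self.beta_),
            se=float(self.se_),
            ci_low=float(self.ci_low_),
            ci_high=float(self.ci_high_),
            pval=float(self.pval_),
            n_snps=self.n_snps_,
            or_=math.nan,
            or_ci_low=math.nan,
            or_ci_high=math.nan,
            intercept=getattr(self, "intercept_", None),
            intercept_se=getattr(self, "intercept_se_", None),
            intercept_pval=getattr(self, "intercept_pval_", None),
        )
        return to_odds_ratio(est, level=level)


def _ivw_fixed(ratio, ratio_se):
    w = 1.0 / ratio_se**2
    beta = float(np.sum(w * ratio) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return beta, se, w


class IVWEstimator(_MRRegressorBase):
    """Inverse-variance-weighted estimate of the causal effect.

    ``mode="fixed"`` is the classic fixed-effects IVW: the precision-weighted
    mean of the Wald ratios.  ``mode="mre"`` is the multiplicative
    random-effects variant: the same point estimate with the standard error
    inflated by sqrt(Q/(J-1)) when Cochran's Q exceeds its degrees of
    freedom (under-dispersion never shrinks the SE).
    """

    def __init__(self, mode: str = "fixed"):
        self.mode = mode

    @property
    def method(self) -> str:
        return {"fixed": "IVW_FE", "mre": "IVW_MRE"}[self.mode]

    @property
    def _min_snps(self) -> int:
        return 1 if self.mode == "fixed" else 2

    def _estimate(self, gamma, se_gamma, Gamma, se_Gamma, ratio, ratio_se):
        if self.mode not in ("fixed", "mre"):
            raise ValueError(f"mode must be 'fixed' or 'mre', got {self.mode!r}")
        beta, se_fe, w = _ivw_fixed(ratio, ratio_se)
        j = ratio.size
        q = float(np.sum(w * (ratio - beta) ** 2))
        self.q_ = q
        if self.mode == "mre":
            se = se_fe * max(1.0, math.sqrt(q / (j - 1)))
        else:
            se = se_fe
        self.beta_, self.se_ = beta, se
        self.pval_ = float(2.0 * stats.norm.sf(abs(beta) / se))


class EggerEstimator(_MRRegressorBase):
    """MR-Egger: weighted regression of Gamma on gamma with an intercept.

    Each pair is first oriented so gamma_j >= 0 (the estimate is invariant to
    the reported effect allele).  The slope is the pleiotropy-adjusted causal
    effect under the InSIDE assumption; the intercept estimates the average
    directional pleiotropic effect, and its test is the standard pleiotropy
    screen.  SEs are scaled by max(1, residual SD); p-values use the t
    distribution with J-2 degrees of freedom.
    """

    _min_snps = 3

    @property
    def method(self) -> str:
        return "EGGER"

    def _estimate(self, gamma, se_gamma, Gamma, se_Gamma, ratio, ratio_se):
        flip = np.sign(gamma)
        flip[flip == 0] = 1.0
        x = gamma * flip
        y = Gamma * flip
        w = 1.0 / se_Gamma**2
        j = x.size
        X = np.column_stack([np.ones(j), x])
        xtwx = X.T @ (w[:, None] * X)
        xtwy = X.T @ (w * y)
        coef = np.linalg.solve(xtwx, xtwy)
        resid = y - X @ coef
        rss_w = float(np.sum(w * resid**2))
        phi = rss_w / (j - 2)
        cov_unscaled = np.linalg.inv(xtwx)
        scale = max(1.0, math.sqrt(phi))
        ses = np.sqrt(np.diag(cov_unscaled)) * scale
        self.intercept_, self.beta_ = float(coef[0]), float(coef[1])
        self.intercept_se_, self.se_ = float(ses[0]), float(ses[1])
        df = j - 2
        self.pval_ = float(2.0 * stats.t.sf(abs(self.beta_) / self.se_, df))
        self.intercept_pval_ = float(
            2.0 * stats.t.sf(abs(self.intercept_) / self.intercept_se_, df)
        )
        self.df_resid_ = df
        self.q_ = rss_w  # Rucker's Q for the Egger model


def weighted_median_point(ratio, weights) -> float:
    """Weighted median by linear interpolation of cumulative weight midpoints.

    With normalized weights w'_j sorted by ratio, the cumulative midpoint of
    SNP j is p_j = sum_{k<=j} w'_k - w'_j/2; the estimate interpolates the
    sorted ratios against p at p = 0.5.
    """
    ratio = np.asarray(ratio, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(ratio, kind="stable")
    r = ratio[order]
    w = weights[order] / weights.sum()
    p = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, p, r))


class _BootstrapMixin:
    def _bootstrap_se(self, point_fn, gamma, se_gamma, Gamma, se_Gamma):
        if self.n_boot < 2:
            return math.nan
        rng = np.random.default_rng(self.random_state)
        draws = np.empty(self.n_boot)
        for b in range(self.n_boot):
            g = rng.normal(gamma, se_gamma)
            G = rng.normal(Gamma, se_Gamma)
            g = np.where(g == 0.0, np.finfo(float).tiny, g)
            draws[b] = point_fn(G / g, (se_Gamma / np.abs(g)))
        return float(np.std(draws, ddof=1))


class WeightedMedianEstimator(_MRRegressorBase, _BootstrapMixin):
    """Weighted median of the Wald ratios.

    Consistent when instruments carrying at least half of the total weight
    are valid.  The SE comes from a parametric bootstrap: gamma*_j and
    Gamma*_j are redrawn from normals centred at the observed effects with
    their standard errors and the estimate recomputed ``n_boot`` times.
    """

    _min_snps = 3

    def __init__(self, n_boot: int = 1000, random_state: int | None = None):
        self.n_boot = n_boot
        self.random_state = random_state

    @property
    def method(self) -> str:
        return "WEIGHTED_MEDIAN"

    @staticmethod
    def _point(ratio, ratio_se):
        return weighted_median_point(ratio, 1.0 / ratio_se**2)

    def _estimate(self, gamma, se_gamma, Gamma, se_Gamma, ratio, ratio_se):
        self.beta_ = self._point(ratio, ratio_se)
        self.se_ = self._bootstrap_se(self._point, gamma, se_gamma, Gamma, se_Gamma)
        self.pval_ = float(2.0 * stats.norm.sf(abs(self.beta_) / self.se_))


class WeightedModeEstimator(_MRRegressorBase, _BootstrapMixin):
    """Weighted mode: the Wald-ratio value maximising a weighted normal-kernel
    density.

    Consistent when the largest group of instruments sharing one ratio value
    is valid (zero modal pleiotropy).  Bandwidth is ``phi * 0.9 *
    min(sd, IQR/1.34) * J^(-1/5)`` on the ratios (when the IQR collapses to
    zero the SD alone is used); the density is evaluated on a 512-point grid
    spanning [min - 3h, max + 3h].  SE by the same parametric bootstrap as
    the weighted median.
    """

    _min_snps = 3
    _grid_points = 512

    def __init__(self, phi: float = 1.0, n_boot: int = 1000, random_state: int | None = None):
        self.phi = phi
        self.n_boot = n_boot
        self.random_state = random_state

    @property
    def method(self) -> str:
        return "WEIGHTED_MODE"

    def _point(self, ratio, ratio_se):
        ratio = np.asarray(ratio, dtype=float)
        w = 1.0 / np.asarray(ratio_se, dtype=float) ** 2
        w = w / w.sum()
        sd = float(np.std(ratio, ddof=1)) if ratio.size > 1 else 0.0
        q75, q25 = np.percentile(ratio, [75, 25])
        iqr = float(q75 - q25)
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        h = self.phi * 0.9 * spread * ratio.size ** (-1 / 5)
        if h <= 0.0:
            # all ratios identical (or degenerate spread): the mode is that value
            return float(ratio[0]) if sd == 0.0 else float(np.median(ratio))
        grid = np.linspace(ratio.min() - 3 * h, ratio.max() + 3 * h, self._grid_points)
        dens = (w[None, :] * stats.norm.pdf((grid[:, None] - ratio[None, :]) / h)).sum(axis=1)
        return float(grid[np.argmax(dens)])

    def _estimate(self, gamma, se_gamma, Gamma, se_Gamma, ratio, ratio_se):
        self.beta_ = self._point(ratio, ratio_se)
        self.se_ = self._bootstrap_se(self._point, gamma, se_gamma, Gamma, se_Gamma)
        self.pval_ = float(2.0 * stats.norm.sf(abs(self.beta_) / self.se_))


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def ivw(h, mode: str = "fixed", level: float = 0.95) -> MREstimate:
    return IVWEstimator(mode=mode).fit(h).to_estimate(level)


def egger(h, level: float = 0.95) -> MREstimate:
    return EggerEstimator().fit(h).to_estimate(level)


def weighted_median(h, n_boot: int = 1000, seed: int | None = None, level: float = 0.95) -> MREstimate:
    return WeightedMedianEstimator(n_boot=n_boot, random_state=seed).fit(h).to_estimate(level)


def weighted_mode(
    h, phi: float = 1.0, n_boot: int = 1000, seed: int | None = None, level: float = 0.95
) -> MREstimate:
    return (
        WeightedModeEstimator(phi=phi, n_boot=n_boot, random_state=seed)
        .fit(h)
        .to_estimate(level)
    )


def estimates_table(estimates, outcome: str | None = None) -> pd.DataFrame:
    """Tidy (forest-plot-ready) table of estimates."""
    rows = []
    for est in estimates:
        row = {
            "method": est.method,
            "n_snps": est.n_snps,
            "beta": est.beta,
            "se": est.se,
            "ci_low": est.ci_low,
            "ci_high": est.ci_high,
            "pval": est.pval,
            "or": est.or_,
            "or_ci_low": est.or_ci_low,
            "or_ci_high": est.or_ci_high,
        }
        if outcome is not None:
            row = {"outcome": outcome, **row}
        rows.append(row)
    return pd.DataFrame(rows)
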