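"""Heterogeneity, pleiotropy and influence diagnostics.

* Cochran's Q against the IVW fit (df = J-1) and Rucker's Q against the
  Egger fit (df = J-2), with chi-square upper-tail p-values.
* MR-PRESSO: a simulation-based residual-sum-of-squares test.  The observed
  statistic sums each SNP's weighted squared residual around the IVW slope
  fitted *without* that SNP; its null distribution is built by redrawing
  summary statistics from their sampling distributions under the
  no-pleiotropy model.  The global test detects any horizontal pleiotropy;
  the per-SNP outlier test Bonferroni-corrects empirical p-values.
* Leave-one-out: refits the chosen IVW estimator excluding each SNP in turn
  and flags associations driven by a single variant.
* Funnel data: per-SNP ratio vs precision pairs for asymmetry inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import IVWEstimator, MREstimate, EggerEstimator
from .summary_io import HarmonizedSet, as_effect_arrays

__all__ = [
    "HeterogeneityResult",
    "PressoResult",
    "cochran_q",
    "mr_presso",
    "leave_one_out",
    "funnel_data",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    method: str  # "IVW" or "EGGER"
    q: float
    df: int
    pval: float


@dataclass(frozen=True)
class PressoResult:
    rss_obs: float
    global_pval: float
    n_sim: int
    snp_ids: list[str] = field(default_factory=list)
    outlier_pvals: list[float] = field(default_factory=list)  # Bonferroni-corrected
    outlier_flags: list[bool] = field(default_factory=list)
    distortion: float | None = None  # IVW_FE change after removing flagged SNPs


def cochran_q(h, method: str = "IVW") -> HeterogeneityResult:
    """Heterogeneity Q statistic around the IVW or Egger fit."""
    ids, gamma, se_gamma, Gamma, se_Gamma = as_effect_arrays(h)
    j = gamma.size
    if method == "IVW":
        if j < 2:
            raise ValueError("Cochran's Q (IVW) requires at least 2 SNPs")
        fit = IVWEstimator(mode="fixed").fit(h)
        q, df = fit.q_, j - 1
    elif method == "EGGER":
        if j < 3:
            raise ValueError("Rucker's Q (EGGER) requires at least 3 SNPs")
        fit = EggerEstimator().fit(h)
        q, df = fit.q_, j - 2
    else:
        raise ValueError(f"method must be 'IVW' or 'EGGER', got {method!r}")
    return HeterogeneityResult(method, float(q), df, float(stats.chi2.sf(q, df)))


def _loo_slopes(gamma, Gamma, w):
    """IVW slope leaving each SNP out, via sufficient statistics.

    The IVW estimate equals the weighted regression of Gamma on gamma
    through the origin with weights 1/se_Gamma^2, so the leave-one-out
    slopes follow from the totals A = sum w g^2 and B = sum w g Gamma.
    Supports a leading batch dimension.
    """
    a = w * gamma**2
    b = w * gamma * Gamma
    A = a.sum(axis=-1, keepdims=True)
    B = b.sum(axis=-1, keepdims=True)
    return (B - b) / (A - a)


def mr_presso(
    h,
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global pleiotropy test and per-SNP outlier test.

    Observed statistic: RSS = sum_j (Gamma_j - b_(-j) gamma_j)^2 / se_Gamma_j^2
    with b_(-j) the leave-one-out IVW slope.  Null replicates redraw
    gamma*_j ~ N(gamma_j, se_gamma_j) and Gamma*_j ~ N(b_(-j) gamma_j,
    se_Gamma_j) and recompute the statistic identically; empirical p-values
    use the (r+1)/(n+1) convention.  Per-SNP outlier p-values are Bonferroni
    corrected across the J SNPs and flagged below ``outlier_alpha``.
    """
    ids, gamma, se_gamma, Gamma, se_Gamma = as_effect_arrays(h)
    j = gamma.size
    if j < 4:
        raise ValueError(f"MR-PRESSO requires at least 4 SNPs, got {j}")
    w = 1.0 / se_Gamma**2
    b_loo = _loo_slopes(gamma, Gamma, w)
    d_obs = w * (Gamma - b_loo * gamma) ** 2
    rss_obs = float(d_obs.sum())

    rng = np.random.default_rng(seed)
    g_sim = rng.normal(gamma, se_gamma, size=(n_sim, j))
    G_sim = rng.normal(b_loo * gamma, se_Gamma, size=(n_sim, j))
    b_loo_sim = _loo_slopes(g_sim, G_sim, w)
    d_sim = w * (G_sim - b_loo_sim * g_sim) ** 2
    rss_sim = d_sim.sum(axis=1)

    global_pval = (np.count_nonzero(rss_sim >= rss_obs) + 1) / (n_sim + 1)
    per_snp_p = (np.count_nonzero(d_sim >= d_obs[None, :], axis=0) + 1) / (n_sim + 1)
    corrected = np.minimum(per_snp_p * j, 1.0)
    flags = corrected < outlier_alpha

    distortion = None
    if flags.any() and (~flags).sum() >= 1:
        full = IVWEstimator(mode="fixed").fit(h)
        kept = HarmonizedSet.from_arrays(
            gamma[~flags], se_gamma[~flags], Gamma[~flags], se_Gamma[~flags],
            snp_ids=list(np.asarray(ids)[~flags]),
        )
        reduced = IVWEstimator(mode="fixed").fit(kept)
        distortion = float(reduced.beta_ - full.beta_)

    return PressoResult(
        rss_obs=rss_obs,
        global_pval=float(global_pval),
        n_sim=int(n_sim),
        snp_ids=list(np.asarray(ids)),
        outlier_pvals=[float(p) for p in corrected],
        outlier_flags=[bool(f) for f in flags],
        distortion=distortion,
    )


def leave_one_out(
    h, method: str = "mre", alpha: float = 0.05
) -> tuple[list[tuple[str, MREstimate]], bool]:
    """Refit IVW excluding each SNP in turn.

    Returns the per-exclusion estimates and a ``driven_by_single_snp`` flag:
    true iff the full-set estimate is significant at ``alpha`` and removing
    some single SNP either loses significance or flips the sign of beta.
    """
    ids, gamma, se_gamma, Gamma, se_Gamma = as_effect_arrays(h)
    j = gamma.size
    if j < 3:
        raise ValueError(f"leave-one-out requires at least 3 SNPs, got {j}")
    est = IVWEstimator(mode=method)
    full = est.fit(
        HarmonizedSet.from_arrays(gamma, se_gamma, Gamma, se_Gamma, snp_ids=list(ids))
    ).to_estimate()
    results: list[tuple[str, MREstimate]] = []
    driven = False
    for k in range(j):
        keep = np.arange(j) != k
        sub = HarmonizedSet.from_arrays(
            gamma[keep], se_gamma[keep], Gamma[keep], se_Gamma[keep],
            snp_ids=list(np.asarray(ids)[keep]),
        )
        loo_est = IVWEstimator(mode=method).fit(sub).to_estimate()
        results.append((str(ids[k]), loo_est))
        if full.pval < alpha and (
            loo_est.pval >= alpha or np.sign(loo_est.beta) != np.sign(full.beta)
        ):
            driven = True
    return results, driven


def funnel_data(h) -> pd.DataFrame:
    """Plot-ready funnel pairs: per-SNP Wald ratio vs precision 1/ratio_se."""
    ids, gamma, se_gamma, Gamma, se_Gamma = as_effect_arrays(h)
    if np.any(gamma == 0.0):
        raise ValueError("funnel data undefined for zero exposure effects")
    ratio = Gamma / gamma
    precision = np.abs(gamma) / se_Gamma
    return pd.DataFrame({"snp_id": ids, "ratio": ratio, "precision": precision})
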