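"""Statistical power for MR with a binary outcome.

Implements the non-centrality-parameter approximation popularised by the
mRnd calculator.  With case fraction K = n_cases/n_total, target odds ratio
OR and instrument strength R^2 (fraction of exposure variance explained by
the instruments combined):

    b   = K (OR - 1) / (1 + K (OR - 1))        # approx. change in case prob.
    NCP = N R^2 b^2 / (K (1 - K) - b^2)
    power = Phi( sqrt(NCP) - z_{1 - alpha/2} )

The second tail Phi(-sqrt(NCP) - z) is omitted (negligible whenever the
calculation is of practical interest).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = ["PowerQuery", "mr_power_binary", "power_table"]


@dataclass(frozen=True)
class PowerQuery:
    """One power calculation: sample sizes, instrument strength, target OR."""

    n_total: int
    n_cases: int
    r2_xz: float
    or_target: float = 1.3
    alpha: float = 0.05
    label: str = ""

    def validate(self) -> None:
        if not (0 < self.n_cases < self.n_total):
            raise ValueError(
                f"need 0 < n_cases < n_total, got {self.n_cases}/{self.n_total}"
            )
        if not (0.0 < self.r2_xz < 1.0):
            raise ValueError(f"r2_xz must be in (0, 1), got {self.r2_xz}")
        if not (self.or_target > 0):
            raise ValueError(f"or_target must be positive, got {self.or_target}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def mr_power_binary(q: PowerQuery) -> float:
    """Power (fraction in [0, 1]) to detect ``or_target`` at two-sided alpha."""
    q.validate()
    k = q.n_cases / q.n_total
    b = k * (q.or_target - 1.0) / (1.0 + k * (q.or_target - 1.0))
    denom = k * (1.0 - k) - b * b
    if denom <= 0.0:
        raise ValueError(
            "degenerate parameterization: K(1-K) <= b^2 "
            f"(K={k:.4g}, OR={q.or_target})"
        )
    ncp = q.n_total * q.r2_xz * b * b / denom
    z = stats.norm.ppf(1.0 - q.alpha / 2.0)
    return float(stats.norm.cdf(math.sqrt(ncp) - z))


def power_table(queries) -> pd.DataFrame:
    """One row per query with inputs echoed and power in percent."""
    rows = []
    for q in queries:
        rows.append(
            {
                "label": q.label,
                "n_total": q.n_total,
                "n_cases": q.n_cases,
                "r2_xz": q.r2_xz,
                "or_target": q.or_target,
                "alpha": q.alpha,
                "power_pct": 100.0 * mr_power_binary(q),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["label", "n_total", "n_cases", "r2_xz", "or_target", "alpha", "power_pct"],
    )
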