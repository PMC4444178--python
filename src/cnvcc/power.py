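"""Analytic and simulation-based power for the case-control design.

Carrier-frequency power uses the two-sided pooled two-proportion
z-test: the control carrier frequency ``p0`` is converted to the case
frequency ``p1`` on the odds scale (case odds = OR x control odds), and

    power = Phi((|p1 - p0| - z_{1-a/2} SE_0) / SE_1)
          + Phi((-|p1 - p0| - z_{1-a/2} SE_0) / SE_1)

with SE_0 the pooled-variance standard error under the null and SE_1
the unpooled standard error under the alternative.  Burden-regression
power is estimated by Monte-Carlo simulation of capped CNV counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of one analytic power calculation."""

    n_cases: int
    n_controls: int
    control_freq: float
    odds_ratio: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.control_freq < 1):
            raise ValueError("control_freq must be in (0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("sample sizes must be positive")


def case_frequency_from_or(control_freq: float, odds_ratio: float) -> float:
    """Convert a control carrier frequency to the case frequency on the odds scale."""
    odds = odds_ratio * control_freq / (1.0 - control_freq)
    return odds / (1.0 + odds)


def two_proportion_power(spec: PowerSpec, warn: bool = True) -> float:
    """Two-sided power of the pooled two-proportion z-test.

    A warning is emitted when the expected carrier count in either
    group is below 1 (normal approximation unreliable); the value is
    still computed.
    """
    p0 = spec.control_freq
    p1 = case_frequency_from_or(p0, spec.odds_ratio)
    n1, n0 = spec.n_cases, spec.n_controls
    if warn and (n1 * p1 < 1 or n0 * p0 < 1):
        import warnings

        warnings.warn(
            "expected carrier count below 1 in a group; normal approximation unreliable",
            stacklevel=2,
        )
    pbar = (n1 * p1 + n0 * p0) / (n1 + n0)
    se0 = math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n0))
    se1 = math.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0)
    z = stats.norm.ppf(1 - spec.alpha / 2)
    d = abs(p1 - p0)
    return float(stats.norm.cdf((d - z * se0) / se1) + stats.norm.cdf((-d - z * se0) / se1))


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero, as power tables are conventionally printed."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def power_table(
    rows: list[tuple[float, float]],
    n_cases: int,
    n_controls: int,
    alpha: float = 0.05,
    decimals: int = 2,
) -> list[tuple[float, float, float]]:
    """Batch power over (control frequency, odds ratio) pairs, rounded for printing."""
    out = []
    for freq, orr in rows:
        p = two_proportion_power(
            PowerSpec(n_cases=n_cases, n_controls=n_controls, control_freq=freq, odds_ratio=orr, alpha=alpha)
        )
        out.append((freq, orr, round_half_up(p, decimals)))
    return out


def burden_power_simulation(
    n_cases: int,
    n_controls: int,
    or_per_cnv: float,
    count_mean: float,
    cap: int = 20,
    alpha: float = 0.05,
    n_reps: int = 200,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the burden logistic regression.

    Control counts are Poisson(``count_mean``); case counts are drawn
    from the exponentially tilted distribution implied by a logistic
    model with slope log(``or_per_cnv``), which for a Poisson baseline
    is Poisson(``count_mean`` x OR); both are truncated at ``cap``.
    Power is the fraction of replicates with a two-sided slope p below
    ``alpha``.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    if count_mean <= 0:
        raise ValueError("count distribution is degenerate (mean <= 0)")
    rng = np.random.default_rng(seed)
    y = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
    X_int = np.ones(n_cases + n_controls)
    hits = 0
    for _ in range(n_reps):
        k_case = np.minimum(rng.poisson(count_mean * or_per_cnv, n_cases), cap)
        k_ctrl = np.minimum(rng.poisson(count_mean, n_controls), cap)
        k = np.concatenate([k_case, k_ctrl]).astype(float)
        if k.std() == 0:
            continue
        X = np.column_stack([X_int, k])
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            if fit.pvalues[-1] < alpha:
                hits += 1
        except Exception:
            continue
    return hits / n_reps
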