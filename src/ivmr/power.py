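"""Analytic power for two-sample MR with a binary outcome.

Uses the non-centrality approximation for a case-control outcome GWAS: with
total outcome sample N, case fraction K, instrument-explained exposure
variance R², alternative odds ratio OR per SD of exposure (b = ln OR), and
two-sided level α,

    power = Φ( √(N · R² · K(1-K)) · |b|  -  z_{1-α/2} ).

N·K(1-K) is the effective sample size of the logistic score test; R² scales
it down to the variance actually carried by the genetically predicted
exposure.  Several published variants of this calculation differ in how they
handle the alternative-hypothesis variance; this symmetric-variance form is
the one implemented by the widely used online MR power calculator and is
internally consistent with the synthetic-data generator, so analytic power
can be cross-validated against simulated rejection rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy import stats
from scipy.optimize import brentq

from .exceptions import DomainError

__all__ = ["PowerQuery", "mr_power_binary", "min_detectable_or"]


@dataclass(frozen=True)
class PowerQuery:
    """Inputs of the binary-outcome MR power calculation.

    r2 is the fraction of exposure variance explained by the instruments
    (e.g. ``sum(variance_explained(eaf, beta))`` over independent SNPs);
    or_alt is the alternative-hypothesis odds ratio per SD of exposure.
    """

    n_cases: int
    n_controls: int
    r2: float
    or_alt: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise DomainError("n_cases and n_controls must be > 0")
        if not 0.0 < self.r2 < 1.0:
            raise DomainError(f"r2 must be in (0,1), got {self.r2}")
        if not self.or_alt > 0:
            raise DomainError(f"or_alt must be > 0, got {self.or_alt}")
        if not 0.0 < self.alpha < 1.0:
            raise DomainError(f"alpha must be in (0,1), got {self.alpha}")


def mr_power_binary(q: PowerQuery) -> float:
    """Two-sided power of the IVW test at the alternative ``q.or_alt``."""
    n = q.n_cases + q.n_controls
    k = q.n_cases / n
    b = abs(math.log(q.or_alt))
    z_crit = float(stats.norm.ppf(1.0 - q.alpha / 2.0))
    ncp = math.sqrt(n * q.r2 * k * (1.0 - k)) * b
    return float(stats.norm.cdf(ncp - z_crit))


def min_detectable_or(
    n_cases: int,
    n_controls: int,
    r2: float,
    alpha: float = 0.05,
    target_power: float = 0.8,
) -> float:
    """Smallest odds ratio above 1 detectable with at least ``target_power``.

    Solved by root bracketing on ln OR; power is continuous and strictly
    increasing in OR > 1, so the root is unique.
    """
    if not 0.0 < target_power < 1.0:
        raise DomainError(f"target_power must be in (0,1), got {target_power}")
    base = PowerQuery(n_cases, n_controls, r2, 1.5, alpha)
    null_power = mr_power_binary(replace(base, or_alt=1.0 + 1e-12))
    if target_power <= null_power:
        raise DomainError(
            f"target power {target_power} is below the null rejection rate "
            f"{null_power:.3g}; any OR > 1 suffices"
        )

    def gap(log_or: float) -> float:
        return mr_power_binary(replace(base, or_alt=math.exp(log_or))) - target_power

    hi = 0.1
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 50:
            raise DomainError("target power unreachable at any finite odds ratio")
    log_or = brentq(gap, 1e-12, hi, xtol=1e-12)
    return float(math.exp(log_or))
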