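"""Estimation and exact tests on transmission data.

Transmission rates are binomial proportions (k carriers among n scored
offspring); point estimates come with exact Clopper-Pearson confidence
intervals.  The co-transmission test compares the observed coinfected
fraction among offspring of coinfected mothers to the independence
expectation p1*p2 with an exact binomial test (minimum-likelihood two-sided
rule, the convention of R's ``binom.test``).  The protection ratio quantifies
how much an existing infection reduces horizontal acquisition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import InfectionStatus, StrainParams

__all__ = [
    "RateEstimate",
    "BinomialTestResult",
    "estimate_rate",
    "carriage_rate",
    "independence_expectation",
    "cotransmission_test",
    "protection_ratio",
]

# Relative rounding slack when comparing point masses in the minimum-likelihood
# rule; same constant as R's binom.test, so exact ties (e.g. at p0 = 1/2) are
# grouped despite float rounding.
_REL_TIE_TOL = 1.0 + 1e-7


@dataclass(frozen=True)
class RateEstimate:
    """Binomial rate estimate with an exact (Clopper-Pearson) confidence interval."""

    k: int
    n: int
    point: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    @property
    def percent(self) -> int:
        """Point estimate as a whole percent (how single-decimal-free rates are reported)."""
        return int(round(100.0 * self.point))

    @property
    def percent_1dp(self) -> float:
        return round(100.0 * self.point, 1)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n": self.n,
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
        }


@dataclass(frozen=True)
class BinomialTestResult:
    """Exact binomial test of k successes in n trials against null probability p0."""

    k: int
    n: int
    p0: float
    p_value: float
    sidedness: str = "two-sided"

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n": self.n,
            "p0": self.p0,
            "p_value": self.p_value,
            "sidedness": self.sidedness,
        }


def _check_counts(k: int, n: int) -> tuple[int, int]:
    k, n = int(k), int(n)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, n], got k={k}, n={n}")
    return k, n


def estimate_rate(k: int, n: int, level: float = 0.95) -> RateEstimate:
    """Estimate a transmission rate from k carriers among n scored offspring.

    The interval is the exact Clopper-Pearson interval at the requested
    confidence level (default 95%).
    """
    k, n = _check_counts(k, n)
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=level, method="exact")
    return RateEstimate(
        k=k, n=n, point=k / n, ci_low=float(ci.low), ci_high=float(ci.high), level=level
    )


def carriage_rate(statuses, strain: int, level: float = 0.95) -> RateEstimate:
    """Rate estimate of strain carriage from a collection of infection statuses.

    ``statuses`` may contain :class:`InfectionStatus` values or their labels.
    """
    seq = list(statuses)
    if not seq:
        raise ValueError("statuses must be non-empty")
    labels = np.asarray(
        [s.label if isinstance(s, InfectionStatus) else str(s) for s in seq],
        dtype=object,
    )
    known = {s.label for s in InfectionStatus}
    unknown = set(np.unique(labels)) - known
    if unknown:
        raise ValueError(f"unknown infection status label(s): {sorted(unknown)}")
    carriers = [s.label for s in InfectionStatus if s.carries(strain)]
    k = int(np.isin(labels, carriers).sum())
    return estimate_rate(k, len(seq), level=level)


def independence_expectation(params: StrainParams) -> float:
    """Expected co-transmission probability under independence: p1 * p2."""
    return params.p1 * params.p2


def cotransmission_test(
    k: int, n: int, p0: float, sidedness: str = "two-sided"
) -> BinomialTestResult:
    """Exact binomial test of k coinfected offspring among n against p0.

    Two-sided p-values use the minimum-likelihood rule: the sum of Binomial
    (n, p0) point masses no larger than the observed one.  Degenerate nulls
    (p0 of 0 or 1) give a p-value of 1 when the observation is the only
    possible outcome and 0 otherwise.
    """
    k, n = _check_counts(k, n)
    p0 = float(p0)
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    if sidedness not in ("two-sided", "lower", "upper"):
        raise ValueError(f"unknown sidedness {sidedness!r}")

    if p0 == 0.0:
        p = 1.0 if (k == 0 or sidedness == "lower") else 0.0
    elif p0 == 1.0:
        p = 1.0 if (k == n or sidedness == "upper") else 0.0
    elif sidedness == "lower":
        p = float(stats.binom.cdf(k, n, p0))
    elif sidedness == "upper":
        p = float(stats.binom.sf(k - 1, n, p0))
    else:
        pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
        p = float(pmf[pmf <= pmf[k] * _REL_TIE_TOL].sum())
        p = min(1.0, p)
    return BinomialTestResult(k=k, n=n, p0=p0, p_value=p, sidedness=sidedness)


def protection_ratio(rate_uninfected: RateEstimate, rate_infected: RateEstimate) -> float:
    """Fold reduction of horizontal-transfer success caused by a resident infection.

    The ratio of point estimates: acquisition rate into uninfected recipients
    divided by the rate into already-infected recipients.  A zero denominator
    is flagged with a warning and returned as infinity.
    """
    if rate_infected.point == 0.0:
        warnings.warn(
            "acquisition rate into infected recipients is zero; "
            "protection ratio is infinite",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return rate_uninfected.point / rate_infected.point
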