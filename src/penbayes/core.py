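"""Bayesian penetrance point estimates and Wilson-propagated credible intervals.

Penetrance is the probability that a carrier of a risk variant develops the
disease, P(D|G). Given carrier frequencies observed in cases and controls and
the lifetime morbid risk P(D) of the disease, Bayes' rule gives

    P(D|G) = P(G|D) * P(D) / (P(G|D) * P(D) + P(G|D̄) * (1 - P(D)))

where P(G|D) is the carrier frequency among cases and P(G|D̄) among controls.
The ~95% credible interval is obtained by propagating the 2.5th and 97.5th
percentile bounds of each carrier frequency — taken from the Wilson score
interval for a binomial proportion at z standard deviations (default z = 2)
— through the same formula:

    lower = f2.5(cases)  * P(D) / (f2.5(cases)  * P(D) + f97.5(controls) * (1 - P(D)))
    upper = f97.5(cases) * P(D) / (f97.5(cases) * P(D) + f2.5(controls)  * (1 - P(D)))

Pairing the low-case frequency with the high-control frequency (and vice
versa) makes the interval conservative. All outputs are clamped to [0, 1];
a control frequency bound of exactly zero drives the corresponding penetrance
bound to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .errors import InputDomainError, UndefinedEstimateError

__all__ = [
    "CaseControlCounts",
    "BaselineRisk",
    "IntervalConfig",
    "ProportionBounds",
    "PenetranceEstimate",
    "carrier_frequency",
    "penetrance_median",
    "proportion_bounds",
    "credible_interval",
    "estimate_penetrance",
]


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


@dataclass(frozen=True)
class CaseControlCounts:
    """Carrier and total counts for one variant in a case-control sample."""

    carriers_cases: int
    total_cases: int
    carriers_controls: int
    total_controls: int

    def __post_init__(self) -> None:
        for name in ("carriers_cases", "total_cases", "carriers_controls", "total_controls"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool):
                raise InputDomainError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise InputDomainError(f"{name} must be non-negative, got {v}")
        if self.total_cases <= 0 or self.total_controls <= 0:
            raise InputDomainError("total_cases and total_controls must be strictly positive")
        if self.carriers_cases > self.total_cases:
            raise InputDomainError(
                f"carriers_cases ({self.carriers_cases}) exceeds total_cases ({self.total_cases})"
            )
        if self.carriers_controls > self.total_controls:
            raise InputDomainError(
                f"carriers_controls ({self.carriers_controls}) exceeds "
                f"total_controls ({self.total_controls})"
            )

    @property
    def freq_cases(self) -> float:
        return carrier_frequency(self.carriers_cases, self.total_cases)

    @property
    def freq_controls(self) -> float:
        return carrier_frequency(self.carriers_controls, self.total_controls)


@dataclass(frozen=True)
class BaselineRisk:
    """Lifetime morbid risk P(D): the population probability of developing the disease."""

    p_disease: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_disease < 1.0):
            raise InputDomainError(
                f"baseline risk must lie in the open interval (0, 1), got {self.p_disease}"
            )

    @property
    def p_healthy(self) -> float:
        """P(D̄) = 1 - P(D)."""
        return 1.0 - self.p_disease


@dataclass(frozen=True)
class IntervalConfig:
    """Width of the frequency bounds, in standard deviations (mean ± z·σ).

    z_multiplier = 2.0 gives the conventional ~95% (2.5th/97.5th percentile)
    bounds; 1.959964 gives the exact 95% normal quantile.
    """

    z_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if not self.z_multiplier > 0:
            raise InputDomainError(f"z_multiplier must be positive, got {self.z_multiplier}")

    @property
    def alpha(self) -> float:
        """Two-sided tail mass corresponding to z_multiplier."""
        return 2.0 * float(norm.sf(self.z_multiplier))


@dataclass(frozen=True)
class ProportionBounds:
    """A carrier-frequency point estimate with its percentile bounds (f2.5, f97.5)."""

    point: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.point <= self.upper <= 1.0):
            raise InputDomainError(
                f"proportion bounds must satisfy 0 <= lower <= point <= upper <= 1, "
                f"got ({self.lower}, {self.point}, {self.upper})"
            )


@dataclass(frozen=True)
class PenetranceEstimate:
    """Median penetrance P(D|G) with lower/upper credible bounds."""

    median: float
    ci_lower: float
    ci_upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_lower <= self.median <= self.ci_upper <= 1.0):
            raise InputDomainError(
                f"estimate must satisfy 0 <= lower <= median <= upper <= 1, "
                f"got ({self.ci_lower}, {self.median}, {self.ci_upper})"
            )


def carrier_frequency(k: int, n: int) -> float:
    """Observed carrier proportion k/n.

    Carriers are counted per subject (genotype frequency), not per allele.
    """
    if not isinstance(k, int) or not isinstance(n, int) or isinstance(k, bool):
        raise InputDomainError(f"counts must be integers, got k={k!r}, n={n!r}")
    if n <= 0:
        raise InputDomainError(f"sample size must be positive, got {n}")
    if k < 0 or k > n:
        raise InputDomainError(f"carrier count must satisfy 0 <= k <= n, got k={k}, n={n}")
    return k / n


def _bayes(freq_cases: float, freq_controls: float, baseline: BaselineRisk) -> float:
    num = freq_cases * baseline.p_disease
    den = num + freq_controls * baseline.p_healthy
    if den == 0.0:
        raise UndefinedEstimateError(
            "penetrance is undefined when the variant is absent from both cases and controls"
        )
    return _clamp01(num / den)


def penetrance_median(counts: CaseControlCounts, baseline: BaselineRisk) -> float:
    """Point (median) penetrance from observed carrier frequencies via Bayes' rule."""
    return _bayes(counts.freq_cases, counts.freq_controls, baseline)


def proportion_bounds(k: int, n: int, cfg: IntervalConfig = IntervalConfig()) -> ProportionBounds:
    """Wilson score interval for the proportion k/n at z = cfg.z_multiplier.

    The lower bound is exactly 0 when k = 0 and the upper bound exactly 1 when
    k = n; both bounds are clamped to [0, 1].
    """
    point = carrier_frequency(k, n)
    lower, upper = proportion_confint(k, n, alpha=cfg.alpha, method="wilson")
    lower = 0.0 if k == 0 else _clamp01(float(lower))
    upper = 1.0 if k == n else _clamp01(float(upper))
    # float round-off can push a bound a hair past the point estimate
    return ProportionBounds(point=point, lower=min(lower, point), upper=max(upper, point))


def credible_interval(
    counts: CaseControlCounts,
    baseline: BaselineRisk,
    cfg: IntervalConfig = IntervalConfig(),
) -> tuple[float, float]:
    """Credible bounds for the penetrance, Wilson bounds propagated through Bayes' rule."""
    if counts.carriers_cases == 0 and counts.carriers_controls == 0:
        raise UndefinedEstimateError(
            "penetrance is undefined when the variant is absent from both cases and controls"
        )
    cases = proportion_bounds(counts.carriers_cases, counts.total_cases, cfg)
    controls = proportion_bounds(counts.carriers_controls, counts.total_controls, cfg)
    p, q = baseline.p_disease, baseline.p_healthy

    lo_num = cases.lower * p
    lo_den = lo_num + controls.upper * q
    lower = _clamp01(lo_num / lo_den) if lo_den > 0 else 0.0

    up_num = cases.upper * p
    up_den = up_num + controls.lower * q
    upper = _clamp01(up_num / up_den) if up_den > 0 else 1.0

    if lower > upper:  # defensive: cannot occur for valid Wilson bounds
        lower, upper = upper, lower
    return lower, upper


def estimate_penetrance(
    counts: CaseControlCounts,
    baseline: BaselineRisk,
    cfg: IntervalConfig = IntervalConfig(),
) -> PenetranceEstimate:
    """Median penetrance with its credible interval: one full calculator run."""
    median = penetrance_median(counts, baseline)
    lower, upper = credible_interval(counts, baseline, cfg)
    # enforce ordering defensively after clamping
    lower = min(lower, median)
    upper = max(upper, median)
    return PenetranceEstimate(median=median, ci_lower=lower, ci_upper=upper)
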