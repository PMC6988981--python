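"""Agreement statistics between published and recomputed penetrance estimates.

Three descriptive procedures quantify how closely recomputed estimates track
published ones across a set of variants:

* Pearson correlation of the median penetrance values, with a two-tailed
  p-value from the t-transform at n − 2 degrees of freedom.
* The same correlation applied to per-variant coefficients of range,
  (upper − lower) / (upper + lower), a scale-free summary of credible-interval
  width.
* A goodness-of-fit statistic Σ (O − E)² / E with the published medians as
  expected and the recomputed medians as observed. Applying a count-based
  statistic to proportions is descriptive agreement, not inference; with
  near-identical continuous values a literal Yates continuity correction
  (|O − E| reduced by 0.5) zeroes every term, so it is off by default and
  available behind a flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import PenetranceEstimate
from .errors import InputDomainError, UndefinedCoefficientError

__all__ = [
    "ValidationPair",
    "ValidationReport",
    "coefficient_of_range",
    "pearson_r",
    "r_p_value",
    "chi_square_goodness",
    "validate_against_published",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidationPair:
    """A published estimate paired with a recomputed one for the same variant."""

    variant_label: str
    published: PenetranceEstimate
    recomputed: PenetranceEstimate


@dataclass(frozen=True)
class ValidationReport:
    """Summary statistics of published-vs-recomputed agreement."""

    r_median: float
    p_r_median: float
    r_range_coefficient: float
    p_r_range: float
    chi_square: float
    chi_square_p: float
    n_pairs: int


def coefficient_of_range(lower: float, upper: float) -> float:
    """Scale-free interval width (upper − lower) / (upper + lower).

    Undefined when both bounds are zero; scale-invariant otherwise.
    """
    if lower < 0 or upper < 0:
        raise InputDomainError(f"bounds must be non-negative, got ({lower}, {upper})")
    total = upper + lower
    if total == 0:
        raise UndefinedCoefficientError("coefficient of range undefined for a (0, 0) interval")
    return (upper - lower) / total


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation between two equal-length sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputDomainError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise InputDomainError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputDomainError("correlation undefined for a constant sequence")
    return float(stats.pearsonr(x, y).statistic)


def r_p_value(r: float, n: int) -> float:
    """Two-tailed p-value for a correlation r observed on n pairs.

    Uses t = r * sqrt((n − 2) / (1 − r²)) referred to Student's t with n − 2
    degrees of freedom. |r| = 1 returns 0 as the limiting value.
    """
    if abs(r) > 1:
        raise InputDomainError(f"|r| must not exceed 1, got {r}")
    if n < 3:
        raise InputDomainError(f"need n >= 3 pairs, got {n}")
    if abs(r) == 1.0:
        return 0.0
    df = n - 2
    t = r * math.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def chi_square_goodness(
    observed: Sequence[float],
    expected: Sequence[float],
    continuity_correction: bool = False,
) -> tuple[float, int, float]:
    """Goodness-of-fit statistic Σ (O − E)² / E with df = len − 1.

    Returns (statistic, degrees of freedom, p-value). With
    ``continuity_correction`` each |O − E| is reduced by 0.5 (floored at 0)
    before squaring.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise InputDomainError(f"length mismatch: {obs.shape} vs {exp.shape}")
    if obs.size < 2:
        raise InputDomainError(f"need at least 2 categories, got {obs.size}")
    if np.any(exp <= 0):
        raise InputDomainError("expected values must all be strictly positive")
    dev = np.abs(obs - exp)
    if continuity_correction:
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float(np.sum(dev**2 / exp))
    df = obs.size - 1
    return statistic, df, float(stats.chi2.sf(statistic, df))


def validate_against_published(
    pairs: Sequence[ValidationPair],
    continuity_correction: bool = False,
) -> ValidationReport:
    """Run the full agreement workflow over published/recomputed pairs.

    Correlates medians, correlates per-pair coefficients of range, and runs
    the goodness-of-fit comparison with published medians as expected values.
    Pairs whose coefficient of range is undefined on either side are excluded
    from the range correlation (with a logged warning) but kept elsewhere.
    """
    if len(pairs) < 3:
        raise InputDomainError(f"need at least 3 pairs, got {len(pairs)}")

    pub_medians = [p.published.median for p in pairs]
    rec_medians = [p.recomputed.median for p in pairs]

    r_med = pearson_r(rec_medians, pub_medians)
    p_med = r_p_value(r_med, len(pairs))

    pub_cor: list[float] = []
    rec_cor: list[float] = []
    for pair in pairs:
        try:
            pc = coefficient_of_range(pair.published.ci_lower, pair.published.ci_upper)
            rc = coefficient_of_range(pair.recomputed.ci_lower, pair.recomputed.ci_upper)
        except UndefinedCoefficientError:
            logger.warning(
                "excluding %s from range correlation: coefficient of range undefined",
                pair.variant_label,
            )
            continue
        pub_cor.append(pc)
        rec_cor.append(rc)

    r_range = pearson_r(rec_cor, pub_cor)
    p_range = r_p_value(r_range, len(pub_cor))

    chi2, _, chi2_p = chi_square_goodness(
        rec_medians, pub_medians, continuity_correction=continuity_correction
    )

    return ValidationReport(
        r_median=r_med,
        p_r_median=p_med,
        r_range_coefficient=r_range,
        p_r_range=p_range,
        chi_square=chi2,
        chi_square_p=chi2_p,
        n_pairs=len(pairs),
    )
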