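"""Synthetic case-control carrier counts with known true penetrance.

Each replicate draws carriers_cases ~ Binomial(n_cases, f_cases) and
carriers_controls ~ Binomial(n_controls, f_controls) independently — carrier
status per subject, matching the carrier-proportion convention of the
estimator. The analytic penetrance evaluated at the true frequencies is the
ground truth for parameter-recovery and interval-coverage checks. The
generator models sampling noise only: no ascertainment bias, population
stratification, or linkage between variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BaselineRisk, CaseControlCounts
from .errors import InputDomainError, UndefinedEstimateError

__all__ = ["SimulationSpec", "simulate_case_control", "analytic_penetrance"]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one binomial sampling experiment."""

    true_freq_cases: float
    true_freq_controls: float
    n_cases: int
    n_controls: int
    baseline: BaselineRisk
    seed: int
    replicates: int = 1

    def __post_init__(self) -> None:
        for name in ("true_freq_cases", "true_freq_controls"):
            f = getattr(self, name)
            if not (0.0 <= f <= 1.0):
                raise InputDomainError(f"{name} must lie in [0, 1], got {f}")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise InputDomainError("sample sizes must be strictly positive")
        if self.replicates < 1:
            raise InputDomainError(f"replicates must be >= 1, got {self.replicates}")


def simulate_case_control(spec: SimulationSpec) -> list[CaseControlCounts]:
    """Draw ``spec.replicates`` independent case-control count sets.

    Reproducible: the same spec (including seed) always yields the same
    sequence of counts.
    """
    rng = np.random.default_rng(spec.seed)
    carriers_cases = rng.binomial(spec.n_cases, spec.true_freq_cases, spec.replicates)
    carriers_controls = rng.binomial(spec.n_controls, spec.true_freq_controls, spec.replicates)
    return [
        CaseControlCounts(
            carriers_cases=int(kc),
            total_cases=spec.n_cases,
            carriers_controls=int(k0),
            total_controls=spec.n_controls,
        )
        for kc, k0 in zip(carriers_cases, carriers_controls)
    ]


def analytic_penetrance(
    true_freq_cases: float,
    true_freq_controls: float,
    baseline: BaselineRisk,
) -> float:
    """Bayes penetrance formula evaluated at the true carrier frequencies."""
    for name, f in (("true_freq_cases", true_freq_cases), ("true_freq_controls", true_freq_controls)):
        if not (0.0 <= f <= 1.0):
            raise InputDomainError(f"{name} must lie in [0, 1], got {f}")
    num = true_freq_cases * baseline.p_disease
    den = num + true_freq_controls * baseline.p_healthy
    if den == 0.0:
        raise UndefinedEstimateError("penetrance undefined when both true frequencies are zero")
    return min(1.0, max(0.0, num / den))
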