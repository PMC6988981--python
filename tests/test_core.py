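"""Unit and property tests for the Bayes penetrance formula and Wilson bounds."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from penbayes import (
    BaselineRisk,
    CaseControlCounts,
    InputDomainError,
    IntervalConfig,
    UndefinedEstimateError,
    carrier_frequency,
    credible_interval,
    estimate_penetrance,
    penetrance_median,
    proportion_bounds,
)


def wilson_oracle(k: int, n: int, z: float) -> tuple[float, float]:
    """Closed-form Wilson score interval, written out independently."""
    z2 = z * z
    center = (k + z2 / 2.0) / (n + z2)
    half = z * math.sqrt(k * (n - k) / n + z2 / 4.0) / (n + z2)
    return center - half, center + half


class TestCarrierFrequency:
    @pytest.mark.parametrize(
        "k, n, expected",
        [(5, 1000, 0.005), (0, 100, 0.0), (7918, 7918, 1.0), (10, 1000, 0.01)],
    )
    def test_ratio(self, k, n, expected):
        assert carrier_frequency(k, n) == expected

    @pytest.mark.parametrize("k, n", [(1, 0), (-1, 10), (11, 10), (0, -5)])
    def test_domain_errors(self, k, n):
        with pytest.raises(InputDomainError):
            carrier_frequency(k, n)


class TestPenetranceMedian:
    def test_equal_frequencies_cancel_to_baseline(self):
        counts = CaseControlCounts(10, 1000, 10, 1000)
        assert penetrance_median(counts, BaselineRisk(0.007)) == pytest.approx(
            0.007, abs=1e-12
        )

    def test_zero_control_frequency_gives_certainty(self):
        counts = CaseControlCounts(10, 1000, 0, 1000)
        assert penetrance_median(counts, BaselineRisk(0.3)) == 1.0

    def test_worked_example(self, example_counts, one_percent_baseline):
        # 0.01*0.01 / (0.01*0.01 + 0.005*0.99) = 0.0001 / 0.00505
        assert penetrance_median(example_counts, one_percent_baseline) == pytest.approx(
            0.0001 / 0.00505, abs=1e-12
        )

    def test_both_arms_zero_is_undefined(self):
        counts = CaseControlCounts(0, 1000, 0, 1000)
        with pytest.raises(UndefinedEstimateError):
            penetrance_median(counts, BaselineRisk(0.01))

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_baseline(self, p):
        with pytest.raises(InputDomainError):
            BaselineRisk(p)

    @given(
        k=st.integers(0, 200),
        n=st.integers(200, 5000),
        kc=st.integers(1, 200),
        p=st.floats(0.001, 0.5),
    )
    def test_baseline_cancellation_identity(self, k, n, kc, p):
        """Identical case/control frequencies always return the baseline itself."""
        counts = CaseControlCounts(max(k, 1), n, max(k, 1), n)
        assert penetrance_median(counts, BaselineRisk(p)) == pytest.approx(p, abs=1e-12)

    @given(
        k1=st.integers(1, 99),
        delta=st.integers(1, 50),
        kc=st.integers(1, 100),
        p=st.floats(0.001, 0.2),
    )
    def test_strictly_monotone_in_case_carriers(self, k1, delta, kc, p):
        b = BaselineRisk(p)
        lo = penetrance_median(CaseControlCounts(k1, 1000, kc, 1000), b)
        hi = penetrance_median(CaseControlCounts(k1 + delta, 1000, kc, 1000), b)
        assert hi > lo

    @given(
        kc1=st.integers(1, 99),
        delta=st.integers(1, 50),
        k=st.integers(1, 100),
        p=st.floats(0.001, 0.2),
    )
    def test_strictly_antitone_in_control_carriers(self, kc1, delta, k, p):
        b = BaselineRisk(p)
        hi = penetrance_median(CaseControlCounts(k, 1000, kc1, 1000), b)
        lo = penetrance_median(CaseControlCounts(k, 1000, kc1 + delta, 1000), b)
        assert lo < hi


class TestProportionBounds:
    def test_matches_hand_evaluation(self):
        b = proportion_bounds(5, 1000, IntervalConfig(2.0))
        assert b.lower == pytest.approx(0.0021028, abs=5e-6)
        assert b.upper == pytest.approx(0.0118414, abs=5e-6)

    def test_zero_successes_lower_is_exactly_zero(self):
        assert proportion_bounds(0, 100, IntervalConfig(2.0)).lower == 0.0

    def test_all_successes_upper_is_exactly_one(self):
        assert proportion_bounds(100, 100, IntervalConfig(2.0)).upper == 1.0

    def test_symmetric_about_half(self):
        b = proportion_bounds(50, 100, IntervalConfig(2.0))
        assert b.lower + b.upper == pytest.approx(1.0, abs=1e-12)

    def test_oracle_equivalence_full_grid(self):
        """Agreement with the independent closed form on every (k, n), n <= 50."""
        cfg = IntervalConfig(2.0)
        for n in range(1, 51):
            for k in range(0, n + 1):
                got = proportion_bounds(k, n, cfg)
                lo, up = wilson_oracle(k, n, 2.0)
                assert got.lower == pytest.approx(max(lo, 0.0), abs=1e-10)
                assert got.upper == pytest.approx(min(up, 1.0), abs=1e-10)

    @given(k=st.integers(0, 60), n=st.integers(1, 60), z=st.floats(0.5, 3.5))
    def test_bounds_bracket_point(self, k, n, z):
        k = min(k, n)
        b = proportion_bounds(k, n, IntervalConfig(z))
        assert 0.0 <= b.lower <= b.point <= b.upper <= 1.0


class TestCredibleInterval:
    def test_zero_controls_upper_clamps_to_one(self):
        counts = CaseControlCounts(10, 1000, 0, 1000)
        _, upper = credible_interval(counts, BaselineRisk(0.01))
        assert upper == 1.0

    def test_equal_arms_interval_straddles_baseline(self):
        counts = CaseControlCounts(5, 1000, 5, 1000)
        lower, upper = credible_interval(counts, BaselineRisk(0.007))
        assert lower < 0.007 < upper

    def test_worked_example(self, example_counts, one_percent_baseline):
        lower, upper = credible_interval(example_counts, one_percent_baseline)
        assert round(lower, 4) == 0.0046
        assert round(upper, 4) == 0.0817

    def test_worked_example_against_composed_oracle(
        self, example_counts, one_percent_baseline
    ):
        """Hand Wilson bounds pushed through the bound formulas, independently."""
        cl, cu = wilson_oracle(10, 1000, 2.0)
        gl, gu = wilson_oracle(5, 1000, 2.0)
        p, q = 0.01, 0.99
        exp_lower = cl * p / (cl * p + gu * q)
        exp_upper = cu * p / (cu * p + gl * q)
        lower, upper = credible_interval(example_counts, one_percent_baseline)
        assert lower == pytest.approx(exp_lower, abs=1e-12)
        assert upper == pytest.approx(exp_upper, abs=1e-12)


class TestEstimatePenetrance:
    def test_composition(self, example_counts, one_percent_baseline):
        est = estimate_penetrance(example_counts, one_percent_baseline)
        assert est.median == pytest.approx(0.0198, abs=5e-5)
        assert round(est.ci_lower, 4) == 0.0046
        assert round(est.ci_upper, 4) == 0.0817

    def test_equal_arm_median_is_baseline(self):
        counts = CaseControlCounts(7, 500, 7, 500)
        est = estimate_penetrance(counts, BaselineRisk(0.007))
        assert est.median == pytest.approx(0.007, abs=1e-12)
        assert est.ci_lower < 0.007 < est.ci_upper

    @given(
        k=st.integers(0, 80),
        n=st.integers(80, 2000),
        kc=st.integers(0, 80),
        nc=st.integers(80, 2000),
        p=st.floats(0.001, 0.5),
        z=st.floats(0.5, 3.0),
    )
    def test_ordering_invariant(self, k, n, kc, nc, p, z):
        if k == 0 and kc == 0:
            return
        est = estimate_penetrance(
            CaseControlCounts(k, n, kc, nc), BaselineRisk(p), IntervalConfig(z)
        )
        assert 0.0 <= est.ci_lower <= est.median <= est.ci_upper <= 1.0

    @given(
        k=st.integers(1, 50),
        kc=st.integers(1, 50),
        p=st.floats(0.001, 0.3),
        c=st.integers(2, 20),
    )
    def test_larger_samples_never_widen_interval(self, k, kc, p, c):
        """Scaling all counts by c keeps frequencies but shrinks the interval."""
        b = BaselineRisk(p)
        small = estimate_penetrance(CaseControlCounts(k, 1000, kc, 1000), b)
        big = estimate_penetrance(CaseControlCounts(k * c, 1000 * c, kc * c, 1000 * c), b)
        assert big.median == pytest.approx(small.median, abs=1e-12)
        assert (big.ci_upper - big.ci_lower) <= (small.ci_upper - small.ci_lower) + 1e-12

    def test_interval_collapses_onto_median_in_the_large_sample_limit(self):
        b = BaselineRisk(0.01)
        widths = []
        for scale in (1, 100, 10_000, 1_000_000):
            est = estimate_penetrance(
                CaseControlCounts(10 * scale, 1000 * scale, 5 * scale, 1000 * scale), b
            )
            widths.append(est.ci_upper - est.ci_lower)
        assert widths == sorted(widths, reverse=True)
        assert widths[-1] < 5e-4
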