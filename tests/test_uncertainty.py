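"""Lognormal arithmetic: fitting, products, bootstrap sums, combination."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from immunocensus.uncertainty import (
    BootstrapEstimate,
    CorrelationGroup,
    LognormalEstimate,
    bootstrap_sum,
    ci95,
    fit_lognormal_from_normal,
    inverse_variance_combine,
    one_sigma,
    propagate_product,
)

positive = st.floats(min_value=1e-6, max_value=1e12, allow_nan=False)
ferrors = st.floats(min_value=1.0, max_value=10.0, allow_nan=False)


class TestLognormalEstimate:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            LognormalEstimate(-1.0)
        with pytest.raises(ValueError):
            LognormalEstimate(1.0, 0.5)
        with pytest.raises(ValueError):
            LognormalEstimate(0.0, 2.0)  # zero must be exact

    def test_exact_estimate_has_zero_shape(self):
        e = LognormalEstimate(5.0, 1.0)
        assert e.s == 0.0 and e.is_exact


class TestFitLognormalFromNormal:
    def test_zero_uncertainty_identity(self):
        e = fit_lognormal_from_normal(10.0, 0.0)
        assert e.value == 10.0 and e.ferror == 1.0

    def test_moment_matching_values(self):
        # s^2 = ln(1 + 0.25), ferror = exp(s), value = mean exp(-s^2/2)
        e = fit_lognormal_from_normal(100.0, 50.0)
        s2 = math.log(1.25)
        assert e.s**2 == pytest.approx(s2, rel=1e-12)
        assert e.ferror == pytest.approx(math.exp(math.sqrt(s2)), rel=1e-12)
        assert e.value == pytest.approx(100 * math.exp(-s2 / 2), rel=1e-12)
        assert e.ferror == pytest.approx(1.604, abs=5e-4)
        assert e.value == pytest.approx(89.44, abs=5e-3)

    def test_monte_carlo_moments_of_fit(self):
        # The fitted lognormal must reproduce the normal's mean and SD.
        e = fit_lognormal_from_normal(100.0, 50.0)
        rng = np.random.default_rng(11)
        draws = e.value * np.exp(e.s * rng.standard_normal(400_000))
        assert draws.mean() == pytest.approx(100.0, rel=5e-3)
        assert draws.std() == pytest.approx(50.0, rel=2e-2)

    @pytest.mark.parametrize(
        "mean,se", [(-5.0, 1.0), (0.0, 1.0), (5.0, -1.0), (1.0, 4.0)]
    )
    def test_rejects_ill_posed(self, mean, se):
        with pytest.raises(ValueError):
            fit_lognormal_from_normal(mean, se)

    @given(mean=positive, cv=st.floats(min_value=1e-6, max_value=2.9))
    @settings(max_examples=50, deadline=None)
    def test_moment_round_trip(self, mean, cv):
        # below cv ~ 1e-6 the s^2 cancellation hits float eps, so the SD
        # round-trip is only meaningful above it (cv = 0 is tested exactly)
        e = fit_lognormal_from_normal(mean, cv * mean)
        assert e.mean == pytest.approx(mean, rel=1e-12)
        assert e.sd == pytest.approx(cv * mean, rel=1e-9, abs=1e-12)


class TestPropagateProduct:
    def test_exact_factor_is_identity(self):
        out = propagate_product(
            LognormalEstimate(2, 1.5), LognormalEstimate(3, 1.0)
        )
        assert out.value == 6 and out.ferror == pytest.approx(1.5)

    def test_root_sum_of_squares(self):
        out = propagate_product(
            LognormalEstimate(1, 2.0), LognormalEstimate(1, 2.0)
        )
        expected = math.exp(math.sqrt(2) * math.log(2))
        assert out.ferror == pytest.approx(expected, rel=1e-12)
        assert out.ferror == pytest.approx(2.665, abs=5e-4)

    def test_scaling_by_exact_mass(self):
        out = propagate_product(
            LognormalEstimate(1e6, 1.2), LognormalEstimate(73, 1.0)
        )
        assert out.value == pytest.approx(7.3e7)
        assert out.ferror == pytest.approx(1.2)

    def test_matches_monte_carlo_product(self):
        # Analytic 95% CI of the product vs a large-sample MC oracle.
        a, b = LognormalEstimate(10.0, 1.8), LognormalEstimate(3.0, 1.4)
        out = propagate_product(a, b)
        rng = np.random.default_rng(3)
        n = 1_000_000
        draws = (
            a.value * np.exp(a.s * rng.standard_normal(n))
            * b.value * np.exp(b.s * rng.standard_normal(n))
        )
        lo_mc, hi_mc = np.percentile(draws, [2.5, 97.5])
        lo, hi = ci95(out)
        assert lo == pytest.approx(lo_mc, rel=0.03)
        assert hi == pytest.approx(hi_mc, rel=0.03)

    @given(a=positive, b=positive, fa=ferrors, fb=ferrors)
    @settings(max_examples=50, deadline=None)
    def test_commutative_and_dominates_inputs(self, a, b, fa, fb):
        x, y = LognormalEstimate(a, fa), LognormalEstimate(b, fb)
        xy, yx = propagate_product(x, y), propagate_product(y, x)
        assert xy.value == yx.value and xy.ferror == yx.ferror
        assert xy.ferror >= max(fa, fb) - 1e-12

    def test_associative(self):
        xs = [LognormalEstimate(v, f) for v, f in
              [(2, 1.3), (5, 2.1), (0.7, 1.9)]]
        left = propagate_product(propagate_product(xs[0], xs[1]), xs[2])
        right = propagate_product(xs[0], propagate_product(xs[1], xs[2]))
        assert left.value == pytest.approx(right.value, rel=1e-12)
        assert left.ferror == pytest.approx(right.ferror, rel=1e-12)


class TestIntervals:
    def test_exact_estimate_degenerate(self):
        assert ci95(LognormalEstimate(1, 1)) == (1, 1)

    def test_one_sigma_half_to_double(self):
        # ferror = 2: one sigma spans half to double the value.
        assert one_sigma(LognormalEstimate(1, 2)) == (0.5, 2.0)

    def test_ci95_values(self):
        lo, hi = ci95(LognormalEstimate(100, 1.5))
        assert lo == pytest.approx(100 * 1.5**-1.96, rel=1e-12)
        assert hi == pytest.approx(100 * 1.5**1.96, rel=1e-12)
        assert lo == pytest.approx(45.17, abs=0.01)
        assert hi == pytest.approx(221.4, abs=0.1)


class TestBootstrapSum:
    def test_requires_seed_and_inputs(self):
        e = LognormalEstimate(5, 2)
        with pytest.raises(ValueError):
            bootstrap_sum([], seed=1)
        with pytest.raises(ValueError):
            bootstrap_sum([e], seed=None)
        with pytest.raises(ValueError):
            bootstrap_sum([e], n_draws=10, seed=1)

    def test_single_term_reproduces_distribution(self):
        e = LognormalEstimate(5, 2)
        out = bootstrap_sum([e], n_draws=100_000, seed=1)
        assert out.value == 5
        # 95% CI approximately value * ferror^±1.96
        assert out.ci_low == pytest.approx(5 * 2**-1.96, rel=0.03)
        assert out.ci_high == pytest.approx(5 * 2**1.96, rel=0.03)

    def test_independent_sum_matches_mc_oracle(self):
        ests = [LognormalEstimate(1e9, 2), LognormalEstimate(1e9, 2)]
        out = bootstrap_sum(ests, n_draws=1_000_000, seed=2)
        assert out.value == 2e9
        rng = np.random.default_rng(999)  # independent oracle stream
        n = 1_000_000
        s = math.log(2)
        draws = 1e9 * np.exp(s * rng.standard_normal(n)) + 1e9 * np.exp(
            s * rng.standard_normal(n)
        )
        lo_mc, hi_mc = np.percentile(draws, [2.5, 97.5])
        assert out.ci_low == pytest.approx(lo_mc, rel=0.03)
        assert out.ci_high == pytest.approx(hi_mc, rel=0.03)

    def test_correlated_group_equals_scaled_single(self):
        # Perfect correlation collapses to one scaled variable: bit-identical
        # draws, hence identical CI, for the same seed.
        pair = [LognormalEstimate(1e9, 2), LognormalEstimate(1e9, 2)]
        grouped = bootstrap_sum(
            pair, [CorrelationGroup("g", ["0", "1"])], n_draws=20_000, seed=3
        )
        single = bootstrap_sum([LognormalEstimate(2e9, 2)], n_draws=20_000,
                               seed=3)
        assert grouped.value == single.value
        assert grouped.ci_low == single.ci_low
        assert grouped.ci_high == single.ci_high
        # and is wider than the independent sum
        independent = bootstrap_sum(pair, n_draws=20_000, seed=3)
        assert grouped.ci_high - grouped.ci_low > (
            independent.ci_high - independent.ci_low
        )

    def test_reproducible_bit_for_bit(self):
        ests = [LognormalEstimate(10, 1.5), LognormalEstimate(3, 2.5)]
        a = bootstrap_sum(ests, n_draws=1000, seed=42)
        b = bootstrap_sum(ests, n_draws=1000, seed=42)
        assert (a.value, a.ferror, a.ci_low, a.ci_high) == (
            b.value, b.ferror, b.ci_low, b.ci_high
        )

    @given(f=st.floats(min_value=1.05, max_value=4.0))
    @settings(max_examples=20, deadline=None)
    def test_ci_width_nondecreasing_in_ferror(self, f):
        base = [LognormalEstimate(10, 1.2), LognormalEstimate(10, 1.2)]
        wider = [LognormalEstimate(10, 1.2 * f), LognormalEstimate(10, 1.2)]
        w0 = bootstrap_sum(base, n_draws=5000, seed=8)
        w1 = bootstrap_sum(wider, n_draws=5000, seed=8)
        assert (w1.ci_high - w1.ci_low) >= (w0.ci_high - w0.ci_low) - 1e-9

    def test_duplicate_group_membership_rejected(self):
        ests = [LognormalEstimate(1, 2)] * 2
        groups = [CorrelationGroup("a", ["0"]), CorrelationGroup("b", ["0"])]
        with pytest.raises(ValueError):
            bootstrap_sum(ests, groups, seed=1)


class TestInverseVarianceCombine:
    def test_single_estimate_identity(self):
        e = LognormalEstimate(1e6, 2)
        out = inverse_variance_combine([e])
        assert out.value == e.value and out.ferror == e.ferror

    def test_equal_ferrors_geometric_mean(self):
        out = inverse_variance_combine(
            [LognormalEstimate(1e6, 2), LognormalEstimate(4e6, 2)]
        )
        assert out.value == pytest.approx(2e6, rel=1e-12)
        assert out.ferror == pytest.approx(
            math.exp(math.log(2) / math.sqrt(2)), rel=1e-12
        )
        assert out.ferror == pytest.approx(1.6325, abs=5e-4)

    def test_precise_estimate_dominates(self):
        # log-weight ratio (1/ln^2 1.1) : (1/ln^2 10) ~ 583:1
        out = inverse_variance_combine(
            [LognormalEstimate(1e6, 1.1), LognormalEstimate(1e8, 10.0)]
        )
        w1, w2 = 1 / math.log(1.1) ** 2, 1 / math.log(10) ** 2
        assert w1 / w2 == pytest.approx(583.6, abs=0.5)
        expected = math.exp(
            (w1 * math.log(1e6) + w2 * math.log(1e8)) / (w1 + w2)
        )
        assert out.value == pytest.approx(expected, rel=1e-12)
        assert out.value < 1.01e6 * 1.1  # lands on the precise side

    def test_exact_estimate_has_infinite_weight(self):
        out = inverse_variance_combine(
            [LognormalEstimate(5.0, 1.0), LognormalEstimate(50.0, 3.0)]
        )
        assert out.value == 5.0 and out.ferror == 1.0

    def test_conflicting_exact_estimates_raise(self):
        with pytest.raises(ValueError):
            inverse_variance_combine(
                [LognormalEstimate(5.0, 1.0), LognormalEstimate(6.0, 1.0)]
            )

    @given(
        vals=st.lists(
            st.tuples(positive, st.floats(min_value=1.01, max_value=8.0)),
            min_size=2, max_size=6,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_betweenness(self, vals):
        ests = [LognormalEstimate(v, f) for v, f in vals]
        out = inverse_variance_combine(ests)
        lo = min(e.value for e in ests)
        hi = max(e.value for e in ests)
        assert lo * (1 - 1e-9) <= out.value <= hi * (1 + 1e-9)

    @pytest.mark.parametrize("k", [2, 3, 7])
    def test_k_replicates_shrink_as_sqrt_k(self, k):
        e = LognormalEstimate(1e6, 2.0)
        out = inverse_variance_combine([e] * k)
        assert out.value == pytest.approx(1e6, rel=1e-12)
        assert out.s == pytest.approx(e.s / math.sqrt(k), rel=1e-12)

    def test_weight_multipliers_shift_result(self):
        a, b = LognormalEstimate(1e6, 2), LognormalEstimate(4e6, 2)
        heavy_b = inverse_variance_combine([a, b], [1.0, 10.0])
        assert heavy_b.value > inverse_variance_combine([a, b]).value
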