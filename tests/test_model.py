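"""Closed-form CTT algebra: reliability, expected TRC, bias, classification,
and the identifiability explorer."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trcsim.model import (
    ConditionSpec,
    InvalidParameterError,
    RELIABILITY_CATEGORIES,
    VarianceComponents,
    classify_reliability,
    equivalent_conditions,
    expected_trc,
    expected_trc_dependent,
    reliability_from_variances,
    trc_bias,
)

unit = st.floats(min_value=0.0, max_value=1.0)
pos_var = st.floats(min_value=1e-3, max_value=1e3)


class TestVarianceComponents:
    @pytest.mark.parametrize(
        "true_var,error_var,expected",
        [(9, 1, 0.90), (1, 1, 0.50), (6, 4, 0.60), (1, 0, 1.0)],
    )
    def test_reliability_ratio(self, true_var, error_var, expected):
        v = VarianceComponents(true_var, error_var)
        assert math.isclose(reliability_from_variances(v), expected, abs_tol=1e-12)

    @pytest.mark.parametrize("true_var,error_var", [(-1, 1), (1, -1), (0, 0)])
    def test_invalid_variances_rejected(self, true_var, error_var):
        with pytest.raises(InvalidParameterError):
            VarianceComponents(true_var, error_var)

    @given(tv=pos_var, ev=pos_var, c=st.floats(min_value=1e-3, max_value=1e3))
    def test_reliability_scale_invariant(self, tv, ev, c):
        """A common rescaling of both variances leaves reliability unchanged."""
        v = VarianceComponents(tv, ev)
        assert math.isclose(
            reliability_from_variances(v),
            reliability_from_variances(v.scaled(c)),
            rel_tol=1e-12,
        )


class TestConditionSpec:
    def test_error_mean_fixed_at_zero(self):
        with pytest.raises(InvalidParameterError):
            ConditionSpec(VarianceComponents(9, 1), 0.8, error_mean=1.0)

    @pytest.mark.parametrize("tau,eps", [(-0.1, 0.0), (1.1, 0.0), (0.5, 1.0), (0.5, -0.2)])
    def test_out_of_range_correlations_rejected(self, tau, eps):
        with pytest.raises(InvalidParameterError):
            ConditionSpec.of(9, 1, tau, eps)


class TestExpectedTRC:
    @pytest.mark.parametrize(
        "tau,rel,expected",
        [(0.7, 0.9, 0.63), (0.8, 0.6, 0.48), (1.0, 0.85, 0.85), (0.5, 1.0, 0.5)],
    )
    def test_attenuation_product(self, tau, rel, expected):
        assert math.isclose(expected_trc(tau, rel), expected, abs_tol=1e-12)

    @pytest.mark.parametrize("tau,rel", [(-0.1, 0.5), (0.5, 1.5), (2.0, 0.5)])
    def test_out_of_range_rejected(self, tau, rel):
        with pytest.raises(InvalidParameterError):
            expected_trc(tau, rel)

    @given(p=unit)
    def test_perfect_stability_identity(self, p):
        """With either factor at 1 the TRC equals the other factor exactly."""
        assert expected_trc(1.0, p) == p
        assert expected_trc(p, 1.0) == p


class TestExpectedTRCDependent:
    @given(tv=pos_var, ev=pos_var, tau=unit)
    def test_reduces_to_product_without_error_dependence(self, tv, ev, tau):
        """r_eps = 0 collapses the mixture onto the attenuation product, exactly."""
        spec = ConditionSpec.of(tv, ev, tau, 0.0)
        rel = reliability_from_variances(spec.variances)
        assert expected_trc_dependent(spec) == expected_trc(tau, rel)

    @given(rho=st.floats(min_value=0.0, max_value=0.99))
    def test_equal_correlations_pass_through(self, rho):
        spec = ConditionSpec.of(3, 2, rho, rho)
        assert math.isclose(expected_trc_dependent(spec), rho, abs_tol=1e-12)

    def test_mixture_value(self):
        spec = ConditionSpec.of(9, 1, 0.6, 0.5)
        assert math.isclose(expected_trc_dependent(spec), 0.59, abs_tol=1e-12)

    @given(
        tv=pos_var,
        ev=pos_var,
        tau=unit,
        eps=st.floats(min_value=0.0, max_value=0.99),
    )
    def test_convex_combination_bounds(self, tv, ev, tau, eps):
        """The mixture lies between its two correlation components."""
        spec = ConditionSpec.of(tv, ev, tau, eps)
        value = expected_trc_dependent(spec)
        assert min(tau, eps) - 1e-12 <= value <= max(tau, eps) + 1e-12

    def test_monotone_in_each_correlation(self):
        base = ConditionSpec.of(6, 4, 0.6, 0.2)
        up_tau = ConditionSpec.of(6, 4, 0.7, 0.2)
        up_eps = ConditionSpec.of(6, 4, 0.6, 0.3)
        assert expected_trc_dependent(up_tau) > expected_trc_dependent(base)
        assert expected_trc_dependent(up_eps) > expected_trc_dependent(base)

    @pytest.mark.parametrize(
        "tau,eps,increasing",
        [(0.8, 0.2, True), (0.2, 0.8, False)],
    )
    def test_variance_ratio_derivative_sign(self, tau, eps, increasing):
        """Raising the variance ratio moves the TRC toward r_tau: the
        derivative in reliability has the sign of (r_tau - r_eps)."""
        lo = expected_trc_dependent(ConditionSpec.of(6, 4, tau, eps))
        hi = expected_trc_dependent(ConditionSpec.of(8, 2, tau, eps))
        assert (hi > lo) == increasing


class TestTRCBias:
    @pytest.mark.parametrize(
        "true_var,error_var,tau,expected",
        [(9, 1, 0.7, 0.27), (9, 1, 0.8, 0.18), (6, 4, 0.8, 0.12)],
    )
    def test_attenuation_bias(self, true_var, error_var, tau, expected):
        spec = ConditionSpec.of(true_var, error_var, tau)
        assert math.isclose(trc_bias(spec), expected, abs_tol=1e-12)

    @given(tv=pos_var, ev=pos_var)
    def test_perfect_stability_is_unbiased(self, tv, ev):
        assert trc_bias(ConditionSpec.of(tv, ev, 1.0)) == 0.0

    @given(tv=pos_var, ev=pos_var, tau=unit)
    def test_independent_error_identity(self, tv, ev, tau):
        """With independent errors, bias = (1 - r_tau) * reliability."""
        spec = ConditionSpec.of(tv, ev, tau)
        rel = reliability_from_variances(spec.variances)
        assert math.isclose(trc_bias(spec), (1.0 - tau) * rel, abs_tol=1e-12)

    @given(
        tv=pos_var,
        ev=pos_var,
        tau=unit,
        eps=st.floats(min_value=0.0, max_value=0.99),
    )
    def test_sign_follows_component_balance(self, tv, ev, tau, eps):
        """bias = (1 - r_tau)*rel - r_eps*(1 - rel): nonnegative exactly when
        the attenuation term outweighs the error-dependence inflation."""
        spec = ConditionSpec.of(tv, ev, tau, eps)
        rel = reliability_from_variances(spec.variances)
        if eps * (1.0 - rel) <= (1.0 - tau) * rel:
            assert trc_bias(spec) >= -1e-12
        else:
            assert trc_bias(spec) <= 1e-12


class TestClassifyReliability:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.95, "excellent"),
            (0.90, "excellent"),
            (0.85, "good"),
            (0.80, "good"),
            (0.70, "acceptable"),
            (0.69, "unacceptable"),
            (-0.2, "unacceptable"),
        ],
    )
    def test_inclusive_bands(self, value, label):
        assert classify_reliability(value).label == label

    @pytest.mark.parametrize("value", [1.5, -1.5])
    def test_out_of_range_rejected(self, value):
        with pytest.raises(InvalidParameterError):
            classify_reliability(value)

    def test_band_bounds(self):
        bounds = {c.label: c.lower_bound for c in RELIABILITY_CATEGORIES}
        assert bounds["acceptable"] == 0.70
        assert bounds["good"] == 0.80
        assert bounds["excellent"] == 0.90


class TestEquivalentConditions:
    def test_commutative_members_at_063(self):
        eq = equivalent_conditions(0.63, grid_resolution=0.05, tolerance=0.005)
        no_dependence = {(t, r) for t, r, e in eq.members if e == 0.0}
        assert (0.7, 0.9) in no_dependence
        assert (0.9, 0.7) in no_dependence

    def test_perfect_trc_requires_perfect_components(self):
        eq = equivalent_conditions(1.0, grid_resolution=0.05, tolerance=0.0)
        assert len(eq) > 0
        assert all(t == 1.0 and r == 1.0 for t, r, _ in eq.members)

    def test_target_060_spans_reliability_categories(self):
        """A TRC near .60 is producible by instruments whose reliabilities sit
        in different interpretation bands: the components are unidentifiable."""
        eq = equivalent_conditions(0.60, grid_resolution=0.05, tolerance=0.005)
        labels = {classify_reliability(r).label for _, r, _ in eq.members}
        assert len(labels) >= 2

    def test_every_member_within_tolerance(self):
        eq = equivalent_conditions(0.45, grid_resolution=0.1, tolerance=0.01)
        assert len(eq) > 0
        for t, r, e in eq.members:
            assert abs(t * r + e * (1 - r) - 0.45) <= 0.01 + 1e-12

    @pytest.mark.parametrize("resolution", [0.0, -0.05, 2.0])
    def test_degenerate_grid_rejected(self, resolution):
        with pytest.raises(InvalidParameterError):
            equivalent_conditions(0.5, grid_resolution=resolution)
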