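"""Closed-form rates, drifts and parameter conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecobehav.model_core import (
    DomainError,
    ModelParams,
    differentials_from_params,
    drift_behavior,
    drift_behavior_rate_form,
    drift_environment,
    environmental_switch_rates,
    impact_mixture,
    no_feedback_drift,
    params_from_differentials,
    social_attractiveness,
    total_switching_rate,
)

PARAM_STRATEGY = st.builds(
    ModelParams,
    gamma_A=st.floats(0.0, 3.0),
    delta_A=st.floats(0.0, 5.0),
    tau=st.floats(0.0, 10.0),
    ell=st.floats(0.01, 1.0),
    l_A=st.floats(0.05, 0.95),
    kappa=st.floats(0.0, 3.0),
)


class TestSocialAttractiveness:
    @pytest.mark.parametrize("x, expected_A, expected_B", [
        (0.0, 1.0, 1.5),   # delta term vanishes at x=0; lambda_B = 1 + 0.5
        (1.0, 1.5, 1.0),   # mirrored at full adoption
        (0.4, 1.2, 1.3),
    ])
    def test_affine_forms(self, default_params, x, expected_A, expected_B):
        lam_A, lam_B = social_attractiveness(x, default_params)
        assert lam_A == pytest.approx(expected_A)
        assert lam_B == pytest.approx(expected_B)

    def test_rejects_frequency_outside_unit_interval(self, default_params):
        with pytest.raises(DomainError):
            social_attractiveness(1.2, default_params)

    def test_clamps_roundoff_excursion(self, default_params):
        lam_A, _ = social_attractiveness(1.0 + 1e-13, default_params)
        assert lam_A == pytest.approx(1.5)


class TestEnvironmentalSwitchRates:
    def test_boundary_rates_vanish(self, default_params):
        p = default_params
        assert environmental_switch_rates(p.l_A, p)[0] == 0.0
        assert environmental_switch_rates(p.l_B, p)[1] == 0.0

    def test_midpoint_value(self):
        p = ModelParams(gamma_A=1, delta_A=0.5, tau=1.0, ell=0.1, l_A=0.7)
        tau_A, tau_B = environmental_switch_rates(0.85, p)
        assert tau_A == pytest.approx(0.15)
        assert tau_B == pytest.approx(0.15)

    @given(params=PARAM_STRATEGY, frac=st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_sum_is_constant_impact_differential(self, params, frac):
        e = params.l_A + frac * (params.l_B - params.l_A)
        tau_A, tau_B = environmental_switch_rates(e, params)
        assert tau_A + tau_B == pytest.approx(
            params.tau * (params.l_B - params.l_A), abs=1e-12)

    def test_rejects_environment_outside_impact_range(self, default_params):
        with pytest.raises(DomainError):
            environmental_switch_rates(0.5, default_params)


class TestDrifts:
    @given(params=PARAM_STRATEGY, x=st.floats(0.0, 1.0),
           frac=st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_expanded_and_rate_forms_agree(self, params, x, frac):
        e = params.l_A + frac * (params.l_B - params.l_A)
        assert drift_behavior(x, e, params) == pytest.approx(
            drift_behavior_rate_form(x, e, params), abs=1e-12)

    def test_boundary_pull_is_impact_differential(self, default_params):
        # p(0, l_B) = tau*(l_B - l_A) > 0 and p(1, l_A) is its negative
        p = default_params
        pull = p.tau * (p.l_B - p.l_A)
        assert drift_behavior(0.0, p.l_B, p) == pytest.approx(pull)
        assert drift_behavior(1.0, p.l_A, p) == pytest.approx(-pull)

    def test_no_feedback_boundaries_are_fixed(self):
        p = ModelParams(gamma_A=1, delta_A=0.5, tau=0.0, ell=0.1, l_A=0.7)
        for x in (0.0, 1.0):
            assert no_feedback_drift(x, p) == 0.0
            assert drift_behavior(x, 0.85, p) == 0.0

    def test_no_feedback_interior_root(self):
        # x* = (delta_B - beta)/(delta_A + delta_B) annihilates p0
        p = params_from_differentials(-0.25, 0.3, tau=0.0, ell=0.1, l_A=0.7)
        x_star = (p.delta_B - p.beta) / (p.delta_A + p.delta_B)
        assert 0 < x_star < 1
        assert no_feedback_drift(x_star, p) == pytest.approx(0.0, abs=1e-14)

    @given(params=PARAM_STRATEGY, x=st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_no_feedback_matches_full_drift_with_tau_zero(self, params, x):
        p0 = params.with_(tau=0.0)
        e = 0.5 * (params.l_A + params.l_B)
        assert no_feedback_drift(x, p0) == pytest.approx(
            drift_behavior(x, e, p0), abs=1e-14)

    def test_environment_drift_vanishes_on_mixture_line(self, default_params):
        for x in (0.0, 0.3, 1.0):
            e = impact_mixture(x, default_params)
            assert drift_environment(x, e, default_params) == 0.0

    def test_environment_relaxes_down_from_ceiling(self, default_params):
        # all-active population perceiving maximal degradation: e falls
        p = default_params
        assert drift_environment(1.0, p.l_B, p) == pytest.approx(
            p.ell * p.l_B * (p.l_A - p.l_B))
        assert drift_environment(1.0, p.l_B, p) < 0

    def test_environment_drift_value(self):
        p = ModelParams(gamma_A=1, delta_A=0.5, tau=0.1, ell=0.1, l_A=0.7)
        assert drift_environment(0.5, 0.7, p) == pytest.approx(0.0105)


class TestTotalSwitchingRate:
    def test_full_adoption_rate_is_tau_times_differential(self):
        p = ModelParams(gamma_A=1, delta_A=0.5, tau=1.0, ell=0.1, l_A=0.7)
        assert total_switching_rate(1.0, p.l_A, p) == pytest.approx(0.3)
        assert total_switching_rate(0.0, p.l_B, p) == pytest.approx(0.3)

    def test_absorbed_boundaries_silent_without_feedback(self):
        p = ModelParams(gamma_A=1, delta_A=0.5, tau=0.0, ell=0.1, l_A=0.7)
        assert total_switching_rate(0.0, 0.85, p) == 0.0
        assert total_switching_rate(1.0, 0.85, p) == 0.0

    @given(params=PARAM_STRATEGY, x=st.floats(0.0, 1.0),
           frac=st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_nonnegative_everywhere(self, params, x, frac):
        e = params.l_A + frac * (params.l_B - params.l_A)
        assert total_switching_rate(x, e, params) >= 0.0


class TestParameterConversions:
    def test_identity_anchors(self):
        p = params_from_differentials(0.0, 0.5, tau=0.1, ell=0.1, l_A=0.7)
        assert p.gamma_A == 1.0
        assert p.delta_A == 0.5

    def test_social_norm_inversion(self):
        p = params_from_differentials(0.0, 0.3, tau=0.1, ell=0.1, l_A=0.7)
        assert p.delta_A == pytest.approx(7.0 / 6.0)

    def test_payoff_differential_is_subtraction(self):
        p = ModelParams(gamma_A=0.75, delta_A=0.5, tau=0.1, ell=0.1, l_A=0.7)
        d = differentials_from_params(p)
        assert d.beta == -0.25
        assert d.nu == 0.5

    @given(beta=st.floats(-1.0, 2.0), nu=st.floats(0.01, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, beta, nu):
        p = params_from_differentials(beta, nu, tau=0.1, ell=0.1, l_A=0.7)
        d = differentials_from_params(p)
        assert d.beta == pytest.approx(beta, abs=1e-12)
        assert d.nu == pytest.approx(nu, abs=1e-12)

    @pytest.mark.parametrize("bad_nu", [0.0, -0.1, 1.5])
    def test_rejects_invalid_norm_threshold(self, bad_nu):
        with pytest.raises(DomainError):
            params_from_differentials(0.0, bad_nu, tau=0.1, ell=0.1, l_A=0.7)

    def test_rejects_negative_payoff(self):
        with pytest.raises(DomainError):
            params_from_differentials(-1.5, 0.5, tau=0.1, ell=0.1, l_A=0.7)


class TestModelParamsValidation:
    def test_requires_impact_ordering(self):
        with pytest.raises(DomainError):
            ModelParams(gamma_A=1, delta_A=0.5, tau=0.1, ell=0.1, l_A=1.2)
        with pytest.raises(DomainError):
            ModelParams(gamma_A=1, delta_A=0.5, tau=0.1, ell=0.1, l_A=-0.1)

    def test_serialization_round_trip(self, bistable_params):
        clone = ModelParams.from_json(bistable_params.to_json())
        assert clone == bistable_params

    def test_from_dict_rejects_unknown_keys(self):
        with pytest.raises(DomainError, match="unknown"):
            ModelParams.from_dict({"gamma_A": 1, "delta_A": 0.5, "tau": 0.1,
                                   "ell": 0.1, "l_A": 0.7, "bogus": 1})

    def test_missing_sensitivity_names_presets(self):
        with pytest.raises(DomainError, match="preset"):
            ModelParams.from_dict({"gamma_A": 1, "delta_A": 0.5, "ell": 0.1,
                                   "l_A": 0.7})
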