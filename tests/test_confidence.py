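"""Confidence posteriors: frozen closed-form values, symmetries, limits, oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from metaconf import (
    BeliefParams,
    GenerativeParams,
    ParameterError,
    ThetaPrior,
    first_order_confidence,
    mc_oracle_confidence,
    postdecisional_confidence,
    prechoice_confidence,
    second_order_confidence,
    second_order_confidence_prechoice,
)
from metaconf.confidence import confidence

B_FO = BeliefParams(1.0, 1.0, 1.0, 1.0, "first_order")
B_PD = BeliefParams(1.0, 1.0, 1.0, 1.0, "postdecisional")
B_SO = BeliefParams(1.0, 1.0, 0.6, 1.0, "second_order")

finite_x = st.floats(-8, 8, allow_nan=False)
actions = st.sampled_from([-1, 1])


class TestFirstOrder:
    @pytest.mark.parametrize(
        "x,a,expected",
        [
            (0.0, -1, 0.5),
            (1.0, 1, 0.88079708),   # logistic(2)
            (-1.0, -1, 0.88079708),  # sign symmetry
        ],
    )
    def test_frozen_values(self, x, a, expected):
        assert first_order_confidence(x, a, B_FO) == pytest.approx(expected, abs=1e-8)

    def test_missing_action_rejected(self):
        with pytest.raises(ParameterError):
            first_order_confidence(1.0, None, B_FO)

    def test_floor_at_half_when_action_matches_sample(self):
        x = np.linspace(-5, 5, 10001)
        a = np.where(x > 0, 1, -1)
        z = first_order_confidence(x, a, B_FO)
        assert z.min() == pytest.approx(0.5, abs=0.0)
        assert np.all(z >= 0.5)


class TestPostdecisional:
    @pytest.mark.parametrize(
        "x,a,expected",
        [
            (0.0, 1, 0.5),
            (-2.0, 1, 0.01798621),  # e^-4 / (1 + e^-4): a detected error
            (2.0, 1, 0.98201379),
        ],
    )
    def test_frozen_values(self, x, a, expected):
        assert postdecisional_confidence(x, a, B_PD) == pytest.approx(expected, abs=1e-8)

    def test_error_detection_possible(self):
        assert postdecisional_confidence(-1.0, 1, B_PD) < 0.5


class TestSecondOrder:
    @pytest.mark.parametrize(
        "belief,x,a,expected",
        [
            # Phi(0.5) / (Phi(0.5) + Phi(-0.5)): action term at equivocal evidence
            (B_SO, 0.0, 1, 0.69146246),
            # rho=1 reduction to the first-order value
            (BeliefParams(1, 1, 1.0, 1), 1.0, 1, 0.88079708),
            # rho=0: only the action discriminates, Phi(1)/(Phi(1)+Phi(-1))
            (BeliefParams(1, 1, 0.0, 1), 0.0, 1, 0.84134475),
        ],
    )
    def test_frozen_values(self, belief, x, a, expected):
        assert second_order_confidence(x, a, belief) == pytest.approx(expected, abs=1e-8)

    def test_error_detection_possible(self):
        assert second_order_confidence(-3.0, 1, B_SO) < 0.5

    def test_nesting_reduction_to_first_order(self):
        """With rho=1 and equal sigmas the second-order posterior collapses."""
        b = BeliefParams(1.3, 1.3, 1.0, 1.0)
        b_fo = BeliefParams(1.3, 1.3, 1.0, 1.0, "first_order")
        for theta in (0.2, 0.7, 1.0):
            x = np.linspace(-6, 6, 101)
            a = np.where(x > 0, 1, -1)
            z_so = second_order_confidence(x, a, b, theta_belief=theta)
            z_fo = first_order_confidence(x, a, b_fo, theta_belief=theta)
            np.testing.assert_allclose(z_so, z_fo, atol=1e-8)

    def test_degenerate_rho_with_unequal_sigmas(self):
        """|rho|=1 with sigma_act != sigma_conf: step-function limit, no NaN."""
        b = BeliefParams(1.0, 2.0, 1.0, 1.0)
        z = second_order_confidence(np.array([-1.0, 0.5, 3.0]), 1, b)
        assert np.all(np.isfinite(z))
        assert np.all((z >= 0) & (z <= 1))

    def test_marginalizing_over_theta_prior(self):
        prior = ThetaPrior.uniform_grid(5)
        z = second_order_confidence(1.0, 1, B_SO, theta_belief=prior)
        # hand-rolled mixture over the grid
        acc = {1: 0.0, -1: 0.0}
        for th, w in zip(prior.values, prior.weights):
            for d in (-1, 1):
                mu_c = d * th + 0.6 * (1.0 - d * th)
                acc[d] += w * norm.pdf(1.0, d * th, 1.0) * norm.cdf(mu_c / 0.8)
        assert z == pytest.approx(acc[1] / (acc[1] + acc[-1]), abs=1e-12)


class TestPrechoice:
    def test_equivocal_evidence_is_half(self):
        assert second_order_confidence_prechoice(0.0, B_SO) == 0.5

    def test_gaussian_posterior_value(self):
        assert second_order_confidence_prechoice(1.0, B_SO) == pytest.approx(
            0.88079708, abs=1e-8)

    def test_always_at_least_half(self):
        x = np.linspace(-6, 6, 501)
        z = second_order_confidence_prechoice(x, B_SO)
        assert np.all(z >= 0.5)

    def test_first_order_pre_equals_post(self):
        x = np.linspace(-4, 4, 201)
        a = np.where(x > 0, 1, -1)
        np.testing.assert_allclose(
            prechoice_confidence(x, B_FO),
            first_order_confidence(x, a, B_FO),
            atol=1e-12,
        )

    def test_query_without_action_dispatches_to_prechoice(self):
        from metaconf.confidence import (
            ConfidenceQuery, evaluate, second_order_predicted_confidence)
        q = ConfidenceQuery(x_conf=1.0, belief=B_SO, a=None)
        assert evaluate(q) == second_order_predicted_confidence(1.0, B_SO)

    def test_predicted_confidence_at_equivocal_evidence(self):
        """Before acting, an uninformative sample still licenses confidence
        near the expected accuracy of the action system: at x=0 the
        prediction equals Phi(0.5) for the canonical parameters, the same
        value the post-choice posterior reaches via the action term."""
        from metaconf.confidence import second_order_predicted_confidence
        z = second_order_predicted_confidence(0.0, B_SO)
        assert z == pytest.approx(0.69146246, abs=1e-8)

    def test_predicted_collapses_to_postchoice_in_first_order_limit(self):
        from metaconf.confidence import second_order_predicted_confidence
        b = BeliefParams(1.0, 1.0, 1.0, 1.0)
        x = np.linspace(-4, 4, 81)
        x = x[x != 0]
        a = np.where(x > 0, 1, -1)
        np.testing.assert_allclose(
            second_order_predicted_confidence(x, b),
            second_order_confidence(x, a, b), atol=1e-10)


class TestSymmetries:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(x=finite_x, rho=st.floats(0, 0.99), sc=st.floats(0.3, 3))
    def test_complement_and_mirror(self, x, rho, sc):
        """z(x, a) = z(-x, -a) for every model; z(x, +1) + z(x, -1) = 1 for
        the models whose posterior does not condition on the action.

        In the second-order model the action itself is evidence, so the two
        conditionings z(x, +1) and z(x, -1) refer to different posteriors
        and need not be complementary (at x = 0, rho = 0 both equal
        Phi(theta/sigma_act)); only the mirror symmetry applies there.
        """
        for b in (
            BeliefParams(1.0, sc, rho, 1.0, "first_order"),
            BeliefParams(1.0, sc, rho, 1.0, "postdecisional"),
        ):
            zp = confidence(x, 1, b)
            zm = confidence(x, -1, b)
            assert zp + zm == pytest.approx(1.0, abs=1e-10)
            assert confidence(-x, -1, b) == pytest.approx(zp, abs=1e-10)
        b_so = BeliefParams(1.0, sc, rho, 1.0, "second_order")
        assert confidence(-x, -1, b_so) == pytest.approx(
            confidence(x, 1, b_so), abs=1e-10)

    @pytest.mark.parametrize("belief", [B_FO, B_PD, B_SO])
    def test_monotone_in_x_conf_for_fixed_action(self, belief):
        x = np.linspace(-8, 8, 1601)
        z = confidence(x, 1, belief)
        assert np.all(np.diff(z) >= -1e-12)
        assert np.all((z >= 0) & (z <= 1))


class TestActionModulation:
    def test_positive_boost_at_equivocal_evidence(self):
        """Conditioning on the taken action lifts confidence above 0.5 at x=0."""
        assert second_order_confidence(0.0, 1, B_SO) > 0.5

    def test_boost_grows_with_sigma_conf(self):
        boosts = [
            second_order_confidence(0.0, 1, BeliefParams(1.0, sc, 0.4, 1.0)) - 0.5
            for sc in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(b2 > b1 for b1, b2 in zip(boosts, boosts[1:]))

    def test_boost_vanishes_as_rho_approaches_one(self):
        boosts = [
            second_order_confidence(0.0, 1, BeliefParams(1.0, 1.0, r, 1.0)) - 0.5
            for r in (0.0, 0.4, 0.8, 0.99)
        ]
        assert all(b2 < b1 for b1, b2 in zip(boosts, boosts[1:]))
        assert boosts[-1] < 0.05


class TestOracle:
    def test_matches_closed_form_at_center(self):
        params = GenerativeParams(1.0, 1.0, 0.6, 1.0)
        z_hat, se = mc_oracle_confidence(params, 0.0, 0.05, 1, 10**6, seed=21)
        assert abs(z_hat - 0.69146246) < 3 * se

    def test_reduction_limit(self):
        params = GenerativeParams(1.0, 1.0, 1.0, 1.0)
        z_hat, se = mc_oracle_confidence(params, 1.0, 0.05, 1, 10**6, seed=22)
        assert abs(z_hat - 0.88079708) < 3 * se + 0.003  # window-width bias

    def test_no_signal_gives_chance(self):
        params = GenerativeParams(1.0, 1.0, 0.0, 0.0)
        z_hat, se = mc_oracle_confidence(params, 0.5, 0.1, 1, 10**6, seed=23)
        assert abs(z_hat - 0.5) < 3 * se

    def test_insufficient_samples_raises(self):
        from metaconf import InsufficientSampleError
        params = GenerativeParams(1.0, 1.0, 0.0, 1.0)
        with pytest.raises(InsufficientSampleError, match=r"\d+"):
            mc_oracle_confidence(params, 7.5, 0.01, 1, 10**5, seed=24)
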