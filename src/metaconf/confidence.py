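"""Confidence posteriors for the three observer models.

Confidence is the posterior probability that the chosen action matched the
world state, z = P(a = d | evidence).  The models condition on different
evidence:

* first-order: z = P(d = a | x_conf) with x_conf = x_act ~ N(d*theta, sigma^2).
  Because the same sample drives the choice, z never falls below 0.5.
* postdecisional: the confidence variable is the sum of two independent
  samples, x_conf ~ N(2*d*theta, 2*sigma^2); z can fall below 0.5 when the
  summed evidence contradicts the choice (error detection).
* second-order: x_conf and the action are distinct, correlated sources.
  The observer inverts the bivariate generative model,

      P(d | x_conf, a, Sigma) ∝ N(x_conf; d*theta, sigma_conf^2)
                                * Phi(a * mu_c(d) / sigma_c),

  with the conditional moments of the decision variable given the
  confidence variable

      mu_c(d) = d*theta + rho * (sigma_act / sigma_conf) * (x_conf - d*theta)
      sigma_c = sigma_act * sqrt(1 - rho^2).

  With rho = 1 and sigma_act = sigma_conf this reduces exactly to the
  first-order model.

All functions are vectorised over ``x_conf`` (and ``a``) and marginalize
over a :class:`~metaconf.model_core.ThetaPrior` when the believed stimulus
strength is uncertain.  Likelihoods are evaluated in log space and combined
with log-sum-exp, so extreme samples (|x_conf| beyond ~8 SD) do not
underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model_core import (
    BeliefParams,
    GenerativeParams,
    InsufficientSampleError,
    ParameterError,
    ThetaPrior,
    child_rng,
    sample_internal_states,
)

__all__ = [
    "ConfidenceQuery",
    "confidence",
    "prechoice_confidence",
    "first_order_confidence",
    "postdecisional_confidence",
    "second_order_confidence",
    "second_order_confidence_prechoice",
    "second_order_predicted_confidence",
    "mc_oracle_confidence",
]


@dataclass(frozen=True)
class ConfidenceQuery:
    """A single confidence evaluation: sample, optional action, beliefs."""

    x_conf: float
    belief: BeliefParams
    a: int | None = None
    theta_belief: float | ThetaPrior | None = None


def _theta_grid(belief: BeliefParams, theta_belief) -> tuple[np.ndarray, np.ndarray]:
    """Resolve the believed stimulus strength into (values, log-weights)."""
    if theta_belief is None:
        theta_belief = belief.theta
    if isinstance(theta_belief, ThetaPrior):
        vals = np.asarray(theta_belief.values)
        w = np.asarray(theta_belief.weights)
        with np.errstate(divide="ignore"):
            return vals, np.log(w)
    return np.array([float(theta_belief)]), np.array([0.0])


def _check_xa(x_conf, a, require_action=True):
    x = np.atleast_1d(np.asarray(x_conf, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ParameterError("x_conf must be finite")
    if not require_action:
        return x, None
    if a is None:
        raise ParameterError("this confidence model conditions on the action; pass a")
    a_arr = np.broadcast_to(np.asarray(a, dtype=int), x.shape).copy()
    if not np.all(np.isin(a_arr, (-1, 1))):
        raise ParameterError("action must be -1 or +1")
    return x, a_arr


def _scalar_like(out: np.ndarray, x_conf):
    if np.ndim(x_conf) == 0:
        return float(out[0])
    return out


def _loglik_gauss(x, thetas, logw, mean_scale, sigma):
    """log sum_theta w * N(x; d*mean_scale*theta, sigma^2) for d = -1, +1.

    Returns (logL_minus, logL_plus), each shaped like ``x``.
    """
    out = []
    for d in (-1.0, 1.0):
        acc = np.full(x.shape, -np.inf)
        for th, lw in zip(thetas, logw):
            if lw == -np.inf:
                continue
            ll = stats.norm.logpdf(x, loc=d * mean_scale * th, scale=sigma)
            acc = np.logaddexp(acc, lw + ll)
        out.append(acc)
    return out[0], out[1]


def _posterior_from_logliks(logl_m, logl_p, a):
    """z = P(d = a | ...) from per-world-state log-evidence."""
    denom = np.logaddexp(logl_m, logl_p)
    log_z = np.where(a > 0, logl_p, logl_m) - denom
    return np.exp(log_z)


# -- first-order -------------------------------------------------------------

def first_order_confidence(x_conf, a, belief: BeliefParams, theta_belief=None):
    """First-order confidence z = P(d = a | x_conf), x_conf ~ N(d*theta, sigma_act^2).

    Because the action is itself the sign of the (shared) sample, z >= 0.5
    whenever ``a == sign(x_conf)``; the model cannot represent having erred.
    """
    x, a_arr = _check_xa(x_conf, a)
    thetas, logw = _theta_grid(belief, theta_belief)
    lm, lp = _loglik_gauss(x, thetas, logw, 1.0, belief.sigma_act)
    return _scalar_like(_posterior_from_logliks(lm, lp, a_arr), x_conf)


# -- postdecisional ----------------------------------------------------------

def postdecisional_confidence(x_conf, a, belief: BeliefParams, theta_belief=None):
    """Postdecisional confidence with summed evidence x_conf ~ N(2*d*theta, 2*sigma^2).

    Confidence may drop below 0.5 when the post-decision sample overturns
    the initial evidence.
    """
    x, a_arr = _check_xa(x_conf, a)
    thetas, logw = _theta_grid(belief, theta_belief)
    lm, lp = _loglik_gauss(x, thetas, logw, 2.0, belief.sigma_act * math.sqrt(2.0))
    return _scalar_like(_posterior_from_logliks(lm, lp, a_arr), x_conf)


# -- second-order ------------------------------------------------------------

def _second_order_logliks(x, belief: BeliefParams, thetas, logw, a_sign,
                          predict=False):
    """Per-world-state log evidence N(x_conf; d theta, s_c^2) * Phi(a mu_c/sigma_c).

    ``a_sign`` is an array of +/-1; with ``predict=True`` the action term
    is evaluated at a = d instead (probability the action system will get
    state d right).  Handles the degenerate |rho| = 1 case (sigma_c = 0)
    by the step-function limit of Phi.
    """
    sa, sc, rho = belief.sigma_act, belief.sigma_conf, belief.rho
    sigma_c = sa * math.sqrt(max(0.0, 1.0 - rho**2))
    out = []
    for d in (-1.0, 1.0):
        acc = np.full(x.shape, -np.inf)
        sign = d if predict else a_sign
        for th, lw in zip(thetas, logw):
            if lw == -np.inf:
                continue
            mu = d * th
            ll = stats.norm.logpdf(x, loc=mu, scale=sc)
            mu_c = mu + rho * (sa / sc) * (x - mu)
            if sigma_c == 0.0:
                s = sign * mu_c
                log_phi = np.where(
                    s > 0, 0.0, np.where(s < 0, -np.inf, math.log(0.5))
                )
            else:
                log_phi = stats.norm.logcdf(sign * mu_c / sigma_c)
            acc = np.logaddexp(acc, lw + ll + log_phi)
        out.append(acc)
    return out[0], out[1]


def second_order_confidence(x_conf, a, belief: BeliefParams, theta_belief=None):
    """Second-order confidence z = P(d = a | x_conf, a, Sigma).

    The observer treats its own action as data: each world state is scored
    by the confidence-variable likelihood times the probability the taken
    action would have occurred under that state.  Error detection (z < 0.5)
    is possible; a nonzero action term keeps z above 0.5 even at
    x_conf = 0 whenever the action is on average reliable.
    """
    x, a_arr = _check_xa(x_conf, a)
    thetas, logw = _theta_grid(belief, theta_belief)
    lm, lp = _second_order_logliks(x, belief, thetas, logw, a_arr)
    return _scalar_like(_posterior_from_logliks(lm, lp, a_arr), x_conf)


def second_order_confidence_prechoice(x_conf, belief: BeliefParams, theta_belief=None):
    """Pre-choice confidence: P(d = sign(x_conf) | x_conf) from x_conf alone.

    Before an action exists there is nothing to condition on, so the
    observer reports confidence in the hypothetical response consistent
    with its confidence sample; the result is always >= 0.5.
    """
    x, _ = _check_xa(x_conf, None, require_action=False)
    thetas, logw = _theta_grid(belief, theta_belief)
    lm, lp = _loglik_gauss(x, thetas, logw, 1.0, belief.sigma_conf)
    a_hyp = np.where(x > 0, 1, -1)
    return _scalar_like(_posterior_from_logliks(lm, lp, a_hyp), x_conf)


def second_order_predicted_confidence(x_conf, belief: BeliefParams,
                                      theta_belief=None):
    """Predicted probability that the upcoming response will be correct.

    z = P(a = d | x_conf) = sum_d P(d | x_conf) * P(a = d | d, x_conf),
    marginalizing the second-order posterior over the not-yet-taken
    action.  This is the coherent rating for a "rate-then-choose" design:
    the observer knows its own action system's reliability, so even an
    uninformative sample (x_conf = 0) yields confidence near the expected
    accuracy rather than 0.5.  In the first-order limit (rho = 1,
    sigma_act = sigma_conf) the action is determined by x_conf and this
    collapses to the post-choice value.
    """
    x, _ = _check_xa(x_conf, None, require_action=False)
    thetas, logw = _theta_grid(belief, theta_belief)
    lm_pred, lp_pred = _second_order_logliks(x, belief, thetas, logw, None,
                                             predict=True)
    lm0, lp0 = _loglik_gauss(x, thetas, logw, 1.0, belief.sigma_conf)
    log_z = np.logaddexp(lm_pred, lp_pred) - np.logaddexp(lm0, lp0)
    return _scalar_like(np.exp(log_z), x_conf)


# -- dispatch ----------------------------------------------------------------

_POST = {
    "first_order": first_order_confidence,
    "postdecisional": postdecisional_confidence,
    "second_order": second_order_confidence,
}


def confidence(x_conf, a, belief: BeliefParams, theta_belief=None):
    """Post-choice confidence under ``belief.model_id``."""
    return _POST[belief.model_id](x_conf, a, belief, theta_belief)


def prechoice_confidence(x_conf, belief: BeliefParams, theta_belief=None):
    """Pre-choice ("rate-choose") confidence under ``belief.model_id``.

    For the first-order and postdecisional models the confidence sample
    carries everything the action could add (d is conditionally
    independent of a given x_conf), so this is the posterior on the
    x_conf-consistent hypothetical response under that model's likelihood;
    in the first-order model it coincides with the post-choice value trial
    by trial.  For the second-order model the action is genuinely
    informative, and the rating a coherent observer gives before acting is
    the predicted probability of responding correctly,
    :func:`second_order_predicted_confidence`.
    """
    x, _ = _check_xa(x_conf, None, require_action=False)
    thetas, logw = _theta_grid(belief, theta_belief)
    mid = belief.model_id
    if mid == "first_order":
        lm, lp = _loglik_gauss(x, thetas, logw, 1.0, belief.sigma_act)
    elif mid == "postdecisional":
        lm, lp = _loglik_gauss(x, thetas, logw, 2.0, belief.sigma_act * math.sqrt(2.0))
    else:
        return second_order_predicted_confidence(x_conf, belief, theta_belief)
    a_hyp = np.where(x > 0, 1, -1)
    return _scalar_like(_posterior_from_logliks(lm, lp, a_hyp), x_conf)


def evaluate(query: ConfidenceQuery):
    """Evaluate a :class:`ConfidenceQuery` (pre-choice when ``a`` is None)."""
    if query.a is None:
        return prechoice_confidence(query.x_conf, query.belief, query.theta_belief)
    return confidence(query.x_conf, query.a, query.belief, query.theta_belief)


# -- Monte-Carlo oracle ------------------------------------------------------

def mc_oracle_confidence(
    params: GenerativeParams,
    x_conf_target: float,
    window: float,
    a: int,
    n: int,
    seed: int,
):
    """Brute-force estimate of P(correct | x_conf ≈ target, action a).

    Simulates ``n`` trials from the true bivariate generative process,
    keeps those whose confidence sample lies within ``window`` of the
    target and whose action equals ``a``, and returns ``(z_hat, se)`` with
    a binomial standard error.  As the window shrinks and n grows this
    converges to the closed-form second-order confidence evaluated with a
    belief equal to the generative parameters — an independent check on
    the analytic inversion.
    """
    if n < 10**5:
        raise ParameterError("oracle needs n >= 1e5 for a stable estimate")
    if window <= 0:
        raise ParameterError("window must be positive")
    if a not in (-1, 1):
        raise ParameterError("action must be -1 or +1")
    rng = child_rng(seed, 0)
    n_sel = 0
    n_corr = 0
    chunk = 2_000_000
    done = 0
    while done < n:
        m = min(chunk, n - done)
        d = rng.choice(np.array([-1.0, 1.0]), size=m)
        x_act, x_conf = sample_internal_states(params, d, rng=rng)
        act = np.where(x_act > 0, 1, -1)
        keep = (np.abs(x_conf - x_conf_target) < window) & (act == a)
        n_sel += int(keep.sum())
        n_corr += int((act[keep] == d[keep]).sum())
        done += m
    if n_sel < 100:
        raise InsufficientSampleError(
            f"only {n_sel} trials fell in the conditioning window; "
            "widen the window or increase n"
        )
    z = n_corr / n_sel
    se = math.sqrt(max(z * (1 - z), 1e-12) / n_sel)
    return z, se
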