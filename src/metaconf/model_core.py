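"""Core generative model: parameters, bivariate evidence sampling, decision rule.

The task is a two-alternative discrimination. On each trial a world state
``d`` in {-1, +1} generates a pair of internal samples, the decision
variable ``x_act`` and the confidence variable ``x_conf``, drawn from a
bivariate Gaussian with mean ``d * theta`` on both axes and covariance

    [[sigma_act**2,                rho * sigma_act * sigma_conf],
     [rho * sigma_act * sigma_conf, sigma_conf**2              ]]

The observer responds ``a = +1`` iff ``x_act > 0`` and ``-1`` otherwise.
Three observer models differ in how the confidence variable arises and in
how confidence is computed from it (see :mod:`metaconf.confidence`):

* ``first_order`` — the confidence variable is the decision variable.
* ``postdecisional`` — the confidence variable is the decision variable
  plus one additional independent evidence sample.
* ``second_order`` — decision and confidence variables are distinct,
  correlated samples; confidence additionally conditions on the action.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "MODEL_IDS",
    "ParameterError",
    "DataError",
    "ConfigError",
    "InsufficientSampleError",
    "GenerativeParams",
    "BeliefParams",
    "ThetaPrior",
    "TRIAL_COLUMNS",
    "child_rng",
    "sample_internal_states",
    "decide",
    "simulate_trials",
    "validate_trial_table",
]

MODEL_IDS = ("first_order", "postdecisional", "second_order")

#: Canonical column order of a trial table.
TRIAL_COLUMNS = [
    "trial", "d", "theta", "x_act", "x_conf", "x_new",
    "a", "z_pre", "z_post", "correct",
]


class ParameterError(ValueError):
    """A model parameter is outside its domain."""


class DataError(ValueError):
    """A trial table violates its invariants."""


class ConfigError(ValueError):
    """An experiment or simulation configuration is invalid."""


class InsufficientSampleError(RuntimeError):
    """Too few Monte-Carlo samples satisfied the conditioning window."""


def _check_params(sigma_act: float, sigma_conf: float, rho: float, theta) -> None:
    if not (np.isfinite(sigma_act) and sigma_act > 0):
        raise ParameterError(f"sigma_act must be positive, got {sigma_act!r}")
    if not (np.isfinite(sigma_conf) and sigma_conf > 0):
        raise ParameterError(f"sigma_conf must be positive, got {sigma_conf!r}")
    if not (np.isfinite(rho) and -1.0 <= rho <= 1.0):
        raise ParameterError(f"rho must lie in [-1, 1], got {rho!r}")
    th = np.asarray(theta, dtype=float)
    if not (np.all(np.isfinite(th)) and np.all(th >= 0) and np.all(th <= 1)):
        raise ParameterError(f"theta must lie in [0, 1], got {theta!r}")


@dataclass(frozen=True)
class GenerativeParams:
    """True parameters of the bivariate-Gaussian evidence process.

    Parameters
    ----------
    sigma_act
        Standard deviation of the decision-variable noise.
    sigma_conf
        Standard deviation of the confidence-variable noise.
    rho
        Correlation of the two samples within a trial.
    theta
        Stimulus strength in [0, 1]; scales the sample mean ``d * theta``.
    """

    sigma_act: float
    sigma_conf: float
    rho: float
    theta: float = 1.0

    def __post_init__(self) -> None:
        _check_params(self.sigma_act, self.sigma_conf, self.rho, self.theta)

    @property
    def cov(self) -> np.ndarray:
        """The implied 2x2 covariance matrix (positive semi-definite)."""
        c = self.rho * self.sigma_act * self.sigma_conf
        return np.array([[self.sigma_act**2, c], [c, self.sigma_conf**2]])


@dataclass(frozen=True)
class BeliefParams:
    """The observer's assumed (hyper)parameters and model class.

    These are the values plugged into the model inversion when computing
    confidence.  They may differ from the generative parameters, which is
    how systematic over- and underconfidence arises.
    """

    sigma_act: float
    sigma_conf: float
    rho: float
    theta: float = 1.0
    model_id: str = "second_order"

    def __post_init__(self) -> None:
        _check_params(self.sigma_act, self.sigma_conf, self.rho, self.theta)
        if self.model_id not in MODEL_IDS:
            raise ParameterError(
                f"model_id must be one of {MODEL_IDS}, got {self.model_id!r}"
            )

    @classmethod
    def from_generative(
        cls, params: GenerativeParams, model_id: str = "second_order"
    ) -> "BeliefParams":
        """A belief matching the generative parameters (well-calibrated observer)."""
        return cls(params.sigma_act, params.sigma_conf, params.rho,
                   params.theta, model_id)

    def with_(self, **kw) -> "BeliefParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class ThetaPrior:
    """Discrete prior over stimulus strength used when theta is unknown.

    The observer marginalizes its likelihoods over this prior; the
    simulator can also draw per-trial theta values from it.
    """

    values: tuple
    weights: tuple

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if v.size == 0:
            raise ConfigError("theta prior must contain at least one value")
        if v.size != w.size:
            raise ConfigError("values and weights must have equal length")
        if np.any(v < 0) or np.any(v > 1):
            raise ParameterError("theta values must lie in [0, 1]")
        if v.size > 1 and not np.all(np.diff(v) > 0):
            raise ConfigError("theta values must be strictly increasing")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ConfigError("weights must be nonnegative and sum to 1")
        object.__setattr__(self, "values", tuple(float(x) for x in v))
        object.__setattr__(self, "weights", tuple(float(x) for x in w))

    @classmethod
    def uniform_grid(cls, n: int = 20, low: float = 0.0, high: float = 1.0) -> "ThetaPrior":
        """Uniform prior on ``n`` equally spaced strengths covering [low, high]."""
        vals = np.linspace(low, high, n)
        return cls(tuple(vals), tuple(np.full(n, 1.0 / n)))

    @classmethod
    def fixed(cls, theta: float) -> "ThetaPrior":
        return cls((float(theta),), (1.0,))

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(np.asarray(self.values), size=n, p=np.asarray(self.weights))


# -- seeding -----------------------------------------------------------------

def child_rng(seed: int, stage: int) -> np.random.Generator:
    """Child generator ``stage`` of root ``seed``.

    Children are spawned as ``SeedSequence(seed, spawn_key=(stage,))`` so a
    single root seed deterministically fans out to independent streams
    indexed by a stage counter.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


# -- sampling and decision ---------------------------------------------------

def sample_internal_states(
    params: GenerativeParams,
    d,
    n: int | None = None,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    base_normals: tuple[np.ndarray, np.ndarray] | None = None,
):
    """Draw paired internal samples (x_act, x_conf) given world state(s) ``d``.

    ``d`` may be a scalar (replicated ``n`` times) or an array.  The pair is
    built from two standard-normal streams z1, z2 as

        x_act  = d*theta + sigma_act * z1
        x_conf = d*theta + sigma_conf * (rho*z1 + sqrt(1-rho^2)*z2)

    which realises the target covariance exactly, including |rho| = 1.
    ``base_normals`` lets callers share the underlying noise across model
    variants for paired comparisons.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim == 0:
        if n is None or n < 1:
            raise ParameterError("n must be >= 1 when d is scalar")
        d = np.full(int(n), float(d))
    if not np.all(np.isin(d, (-1.0, 1.0))):
        raise ParameterError("world state d must be -1 or +1")
    if base_normals is None:
        if rng is None:
            if seed is None:
                raise ParameterError("provide seed, rng or base_normals")
            rng = np.random.default_rng(seed)
        z1 = rng.standard_normal(d.size)
        z2 = rng.standard_normal(d.size)
    else:
        z1, z2 = base_normals
    mu = d * params.theta
    x_act = mu + params.sigma_act * z1
    x_conf = mu + params.sigma_conf * (
        params.rho * z1 + math.sqrt(max(0.0, 1.0 - params.rho**2)) * z2
    )
    return x_act, x_conf


def decide(x_act):
    """Binary choice: +1 iff the decision variable exceeds zero, else -1.

    A tie at exactly zero maps to -1.  Accepts scalars or arrays.
    """
    x = np.asarray(x_act, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ParameterError("x_act must be finite")
    a = np.where(x > 0, 1, -1)
    if np.isscalar(x_act) or np.ndim(x_act) == 0:
        return int(a)
    return a.astype(int)


def _generate_states(model_id, params, d, theta, z1, z2):
    """Per-model internal states from shared standard normals.

    Returns (x_act, x_conf, x_new); x_new is NaN except for the
    postdecisional model.
    """
    mu = d * theta
    x_new = np.full(d.size, np.nan)
    if model_id == "first_order":
        x_act = mu + params.sigma_act * z1
        x_conf = x_act.copy()
    elif model_id == "postdecisional":
        x_act = mu + params.sigma_act * z1
        x_new = mu + params.sigma_act * z2
        x_conf = x_act + x_new
    elif model_id == "second_order":
        srt = math.sqrt(max(0.0, 1.0 - params.rho**2))
        x_act = mu + params.sigma_act * z1
        x_conf = mu + params.sigma_conf * (params.rho * z1 + srt * z2)
    else:  # pragma: no cover - guarded by BeliefParams validation
        raise ParameterError(f"unknown model_id {model_id!r}")
    return x_act, x_conf, x_new


def simulate_trials(
    params: GenerativeParams,
    theta_schedule,
    n: int,
    belief: BeliefParams,
    seed: int,
    *,
    theta_belief=None,
) -> pd.DataFrame:
    """Simulate ``n`` trials and fill in pre- and post-choice confidence.

    The world state is drawn equiprobably from {-1, +1} (flat prior), the
    stimulus strength from ``theta_schedule`` (a :class:`ThetaPrior` or a
    fixed float), internal states from the generative process selected by
    ``belief.model_id``, actions from the sign rule, and confidence from
    the corresponding model using the belief parameters.

    ``theta_belief`` controls the strength assumed during model inversion:
    by default the schedule itself (a fixed value if the schedule is fixed,
    marginalized over the prior otherwise).
    """
    # local import avoids a module cycle
    from .confidence import confidence as _post_conf
    from .confidence import prechoice_confidence as _pre_conf

    if n < 1:
        raise ParameterError("n must be >= 1")
    if isinstance(theta_schedule, (int, float)):
        theta_schedule = ThetaPrior.fixed(theta_schedule)
    if not isinstance(theta_schedule, ThetaPrior):
        raise ConfigError("theta_schedule must be a float or ThetaPrior")
    if theta_belief is None:
        theta_belief = theta_schedule

    rng = child_rng(seed, 0)
    d = rng.choice(np.array([-1.0, 1.0]), size=n)
    theta = theta_schedule.draw(n, rng)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    x_act, x_conf, x_new = _generate_states(
        belief.model_id, params, d, theta, z1, z2
    )
    a = decide(x_act)
    z_post = _post_conf(x_conf, a, belief, theta_belief)
    z_pre = _pre_conf(x_conf, belief, theta_belief)
    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "d": d.astype(int),
            "theta": theta,
            "x_act": x_act,
            "x_conf": x_conf,
            "x_new": x_new,
            "a": a,
            "z_pre": z_pre,
            "z_post": z_post,
            "correct": a == d.astype(int),
        }
    )


def validate_trial_table(table: pd.DataFrame) -> None:
    """Check a trial table's structural invariants; raise DataError on failure."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    extra = [c for c in table.columns if c not in TRIAL_COLUMNS]
    if missing or extra:
        raise DataError(f"bad trial-table header: missing {missing}, extra {extra}")
    if len(table) == 0:
        return
    if not np.all(np.isin(table["d"], (-1, 1))):
        raise DataError("world state d must be -1 or +1")
    if not np.all(np.isin(table["a"], (-1, 1))):
        raise DataError("action a must be -1 or +1")
    expect_a = np.where(table["x_act"].to_numpy() > 0, 1, -1)
    bad = np.nonzero(table["a"].to_numpy() != expect_a)[0]
    if bad.size:
        raise DataError(
            f"action inconsistent with decision rule at rows {bad[:10].tolist()}"
        )
    bad_c = np.nonzero(
        table["correct"].to_numpy() != (table["a"].to_numpy() == table["d"].to_numpy())
    )[0]
    if bad_c.size:
        raise DataError(f"correct flag inconsistent at rows {bad_c[:10].tolist()}")
    for col in ("z_pre", "z_post"):
        z = table[col].to_numpy(dtype=float)
        present = ~np.isnan(z)
        if np.any((z[present] < 0) | (z[present] > 1)):
            bad_z = np.nonzero(present & ((z < 0) | (z > 1)))[0]
            raise DataError(f"{col} outside [0, 1] at rows {bad_z[:10].tolist()}")
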