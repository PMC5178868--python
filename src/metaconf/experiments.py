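"""Config-driven simulation experiments over the three observer models.

Each experiment is a pure function of its parameters and a seed, returning
tidy pandas tables.  Within an experiment all model variants consume the
same underlying standard-normal noise, so cross-model contrasts are paired.

The experiments:

* ``x_pattern`` — mean confidence by stimulus strength and accuracy (the
  behavioural X-pattern) and by binned internal state, for all three models.
* ``error_surface`` — detected-error fraction over a (sigma_conf, rho)
  grid at fixed task performance.
* ``action_effect`` — pre-choice ("rate-choose") versus post-choice
  ("choose-rate") confidence: bias and sensitivity, over parameter sweeps.
* ``metad_sweep`` — meta-d'/d' and error detection over a
  (sigma_act, sigma_conf) grid at rho = 0.5.
* ``miscalibration`` — calibration curves when the observer's believed
  hyperparameters deviate from the generative ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .confidence import confidence as _post_conf
from .confidence import prechoice_confidence as _pre_conf
from .metrics import (
    RatingScheme,
    bias_and_sensitivity,
    calibration_curve,
    discretize_confidence,
    error_detection_rate,
    fit_meta_d,
    type2_roc,
)
from .model_core import (
    BeliefParams,
    ConfigError,
    GenerativeParams,
    ThetaPrior,
    child_rng,
    decide,
    simulate_trials,
)

__all__ = [
    "ExperimentSpec",
    "EXPERIMENT_IDS",
    "run_x_pattern",
    "run_error_surface",
    "run_action_effect",
    "run_roc_sweep",
    "run_metad_sweep",
    "run_miscalibration",
    "run_experiment",
]

EXPERIMENT_IDS = (
    "x_pattern", "error_surface", "action_effect",
    "roc_sweep", "metad_sweep", "miscalibration",
)


@dataclass(frozen=True)
class ExperimentSpec:
    """Identifier, parameters and seed for one experiment run."""

    experiment_id: str
    n_trials: int = 100_000
    seed: int = 0
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment_id not in EXPERIMENT_IDS:
            raise ConfigError(
                f"unknown experiment {self.experiment_id!r}; "
                f"choose from {EXPERIMENT_IDS}"
            )
        if self.n_trials < 1000:
            raise ConfigError("stochastic experiments need n_trials >= 1000")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentSpec":
        d = dict(d)
        return cls(
            experiment_id=d.pop("experiment_id"),
            n_trials=int(d.pop("n_trials", 100_000)),
            seed=int(d.pop("seed", 0)),
            options=d.pop("options", d),
        )

    @classmethod
    def from_json(cls, path) -> "ExperimentSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# -- shared-noise simulation helper ------------------------------------------

def _simulate_all_models(params: GenerativeParams, theta_prior: ThetaPrior,
                         n: int, seed: int,
                         theta_belief=None) -> dict[str, pd.DataFrame]:
    """Trial tables for the three models built from one shared noise draw.

    The per-trial world state, stimulus strength and the two
    standard-normal streams are common; each model maps them to its own
    internal states, so differences between models are not sampling noise.
    """
    from .model_core import _generate_states

    rng = child_rng(seed, 0)
    d = rng.choice(np.array([-1.0, 1.0]), size=n)
    theta = theta_prior.draw(n, rng)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    if theta_belief is None:
        theta_belief = theta_prior
    out = {}
    for model_id in ("first_order", "postdecisional", "second_order"):
        belief = BeliefParams.from_generative(params, model_id)
        x_act, x_conf, x_new = _generate_states(model_id, params, d, theta, z1, z2)
        a = decide(x_act)
        out[model_id] = pd.DataFrame({
            "trial": np.arange(n),
            "d": d.astype(int),
            "theta": theta,
            "x_act": x_act,
            "x_conf": x_conf,
            "x_new": x_new,
            "a": a,
            "z_pre": _pre_conf(x_conf, belief, theta_belief),
            "z_post": _post_conf(x_conf, a, belief, theta_belief),
            "correct": a == d.astype(int),
        })
    return out


# -- X-pattern ---------------------------------------------------------------

def run_x_pattern(spec: ExperimentSpec) -> dict[str, pd.DataFrame]:
    """Confidence vs stimulus strength and vs internal state, by accuracy.

    Stimulus strength is drawn per trial from a uniform grid on [0, 1]
    which the observer does not know, so confidence marginalizes its
    likelihoods over the same grid.  Returns ``by_theta`` (mean confidence
    per model, theta, correctness) and ``by_state`` (mean confidence per
    model, x_conf bin, correctness; 25 equal-count bins).
    """
    opt = spec.options
    params = GenerativeParams(
        opt.get("sigma_act", 1.0), opt.get("sigma_conf", 1.0),
        opt.get("rho", 0.6), theta=1.0,
    )
    prior = ThetaPrior.uniform_grid(opt.get("n_theta", 20))
    n_state_bins = opt.get("n_state_bins", 25)
    tables = _simulate_all_models(params, prior, spec.n_trials, spec.seed)

    by_theta_rows, by_state_rows = [], []
    for model_id, t in tables.items():
        g = t.groupby(["theta", "correct"])["z_post"].agg(["mean", "count"])
        for (theta, correct), row in g.iterrows():
            by_theta_rows.append({
                "model": model_id, "theta": theta, "correct": bool(correct),
                "mean_confidence": row["mean"], "count": int(row["count"]),
            })
        # equal-count bins of the signed internal state
        edges = np.quantile(t["x_conf"], np.linspace(0, 1, n_state_bins + 1))
        binned = t.assign(
            state_bin=np.searchsorted(edges[1:-1], t["x_conf"], side="right"),
        )
        g2 = binned.groupby(["state_bin", "correct"]).agg(
            x_conf_mean=("x_conf", "mean"),
            mean_confidence=("z_post", "mean"),
            count=("z_post", "count"),
        )
        for (b, correct), row in g2.iterrows():
            by_state_rows.append({
                "model": model_id, "state_bin": int(b),
                "x_conf_mean": row["x_conf_mean"], "correct": bool(correct),
                "mean_confidence": row["mean_confidence"],
                "count": int(row["count"]),
            })
    return {
        "by_theta": pd.DataFrame(by_theta_rows),
        "by_state": pd.DataFrame(by_state_rows),
    }


# -- error-detection surface -------------------------------------------------

def run_error_surface(spec: ExperimentSpec) -> pd.DataFrame:
    """Detected-error fraction over a (sigma_conf, rho) grid, sigma_act = 1.

    Task performance is constant across the grid (theta = 1, sigma_act = 1,
    ~84% correct); only the confidence channel varies.  Errors are
    "detected" when post-choice confidence falls below 0.5.
    """
    opt = spec.options
    sigma_confs = np.asarray(opt.get("sigma_conf_grid",
                                     np.round(np.linspace(0.25, 2.0, 8), 4)))
    rhos = np.asarray(opt.get("rho_grid", np.round(np.linspace(0.0, 0.95, 8), 4)))
    rows = []
    for i, sc in enumerate(sigma_confs):
        for j, r in enumerate(rhos):
            params = GenerativeParams(1.0, float(sc), float(r), theta=1.0)
            belief = BeliefParams.from_generative(params, "second_order")
            t = simulate_trials(params, 1.0, spec.n_trials, belief,
                                spec.seed + 1000 * i + j)
            rows.append({
                "sigma_conf": float(sc), "rho": float(r),
                "error_detection_rate": error_detection_rate(t),
                "accuracy": float(t["correct"].mean()),
                "n": spec.n_trials,
            })
    return pd.DataFrame(rows)


# -- action effects ----------------------------------------------------------

def _pre_post_contrast(params: GenerativeParams, model_id: str,
                       n: int, seed: int) -> dict:
    belief = BeliefParams.from_generative(params, model_id)
    t = simulate_trials(params, params.theta, n, belief, seed)
    bias_post, sens_post = bias_and_sensitivity(t, "z_post")
    bias_pre, sens_pre = bias_and_sensitivity(t, "z_pre")
    return {
        "model": model_id,
        "sigma_act": params.sigma_act, "sigma_conf": params.sigma_conf,
        "rho": params.rho,
        "bias_rate_choose": bias_pre, "bias_choose_rate": bias_post,
        "sensitivity_rate_choose": sens_pre, "sensitivity_choose_rate": sens_post,
        "bias_delta": bias_post - bias_pre,
        "sensitivity_delta": sens_post - sens_pre,
        "n": n,
    }


def run_action_effect(spec: ExperimentSpec) -> dict[str, pd.DataFrame]:
    """Choose-rate vs rate-choose confidence for the second-order observer.

    Pre- and post-choice confidence are computed on identical trials.
    Conditioning on the action lowers overall confidence (bias) and raises
    the correct-error confidence gap (sensitivity); a first-order control
    shows neither effect.  Sweeps sigma_conf at rho = 0.6 and rho at
    sigma_conf = 1 (sigma_act = 1, theta = 1 throughout).
    """
    opt = spec.options
    n = spec.n_trials
    sc_grid = np.asarray(opt.get("sigma_conf_grid",
                                 np.round(np.linspace(0.5, 2.0, 6), 4)))
    rho_grid = np.asarray(opt.get("rho_grid", np.round(np.linspace(0.0, 0.9, 6), 4)))
    rows = [
        _pre_post_contrast(GenerativeParams(1.0, 1.0, 0.6), "second_order",
                           n, spec.seed),
        _pre_post_contrast(GenerativeParams(1.0, 1.0, 0.6), "first_order",
                           n, spec.seed + 1),
    ]
    for i, sc in enumerate(sc_grid):
        rows.append(_pre_post_contrast(
            GenerativeParams(1.0, float(sc), 0.6), "second_order",
            n, spec.seed + 10 + i))
    for j, r in enumerate(rho_grid):
        rows.append(_pre_post_contrast(
            GenerativeParams(1.0, 1.0, float(r)), "second_order",
            n, spec.seed + 100 + j))
    return {"contrasts": pd.DataFrame(rows)}


# -- ROC sweeps --------------------------------------------------------------

def run_roc_sweep(spec: ExperimentSpec) -> pd.DataFrame:
    """Type 2 ROC area as sigma_conf (at fixed rho) or rho (at fixed
    sigma_conf) varies, second-order observer, sigma_act = 1, theta = 1.

    More confidence noise or tighter coupling to the decision variable both
    reduce metacognitive sensitivity while task performance is unchanged.
    """
    opt = spec.options
    n_bins = opt.get("n_bins", 10)
    sc_grid = np.asarray(opt.get("sigma_conf_grid", [0.5, 0.75, 1.0, 1.5, 2.0]))
    rho_grid = np.asarray(opt.get("rho_grid", [0.0, 0.25, 0.5, 0.75, 0.95]))
    rows = []
    for i, sc in enumerate(sc_grid):
        params = GenerativeParams(1.0, float(sc), opt.get("rho", 0.5))
        belief = BeliefParams.from_generative(params, "second_order")
        t = simulate_trials(params, 1.0, spec.n_trials, belief, spec.seed + i)
        roc = type2_roc(t, RatingScheme.quantile(n_bins, t["z_post"]))
        rows.append({"sweep": "sigma_conf", "sigma_conf": float(sc),
                     "rho": params.rho, "type2_area": roc.area,
                     "accuracy": float(t["correct"].mean())})
    for j, r in enumerate(rho_grid):
        params = GenerativeParams(1.0, opt.get("sigma_conf", 1.0), float(r))
        belief = BeliefParams.from_generative(params, "second_order")
        t = simulate_trials(params, 1.0, spec.n_trials, belief,
                            spec.seed + 100 + j)
        roc = type2_roc(t, RatingScheme.quantile(n_bins, t["z_post"]))
        rows.append({"sweep": "rho", "sigma_conf": params.sigma_conf,
                     "rho": float(r), "type2_area": roc.area,
                     "accuracy": float(t["correct"].mean())})
    return pd.DataFrame(rows)


# -- meta-d' sweep -----------------------------------------------------------

def run_metad_sweep(spec: ExperimentSpec) -> pd.DataFrame:
    """d', meta-d', their ratio and error detection over (sigma_act, sigma_conf).

    rho is held at 0.5 and theta at 1; each grid cell is one simulated
    dataset fit with the meta-d' model (K = 4 quantile ratings).  Hyper-
    metacognitive sensitivity (ratio > 1) concentrates where
    sigma_conf/sigma_act < 1, alongside high detected-error fractions.
    Failed fits are reported with NaN and counted by the caller.
    """
    opt = spec.options
    grid_n = opt.get("grid_n", 20)
    lo, hi = opt.get("sigma_range", (0.25, 3.0))
    n_bins = opt.get("n_bins", 4)
    sig = np.round(np.linspace(lo, hi, grid_n), 6)
    rows = []
    for i, sa in enumerate(sig):
        for j, sc in enumerate(sig):
            params = GenerativeParams(float(sa), float(sc), 0.5, theta=1.0)
            belief = BeliefParams.from_generative(params, "second_order")
            t = simulate_trials(params, 1.0, spec.n_trials, belief,
                                spec.seed + 1000 * i + j)
            row = {"sigma_act": float(sa), "sigma_conf": float(sc),
                   "ratio_sigma": float(sc / sa),
                   "error_detection_rate": error_detection_rate(t)}
            try:
                fit = fit_meta_d(discretize_confidence(
                    t, RatingScheme.quantile(n_bins, t["z_post"])))
                row.update(d_prime=fit.d_prime, meta_d=fit.meta_d,
                           ratio=fit.ratio)
            except Exception:
                row.update(d_prime=np.nan, meta_d=np.nan, ratio=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


# -- miscalibration ----------------------------------------------------------

#: Generative setting for the hyperparameter-miscalibration experiment.
MISCALIBRATION_TRUTH = GenerativeParams(1.5, 1.0, 0.6, theta=1.0)


def run_miscalibration(spec: ExperimentSpec) -> pd.DataFrame:
    """Calibration curves under mismatched belief hyperparameters.

    The generative process is fixed (sigma_act = 1.5, sigma_conf = 1,
    rho = 0.6); one believed parameter is varied per sweep while the others
    stay at the true values.  Matched beliefs yield an identity-line
    calibration curve; e.g. a believed sigma_act below the true value makes
    actions look more reliable than they are, producing overconfidence.
    """
    opt = spec.options
    truth = MISCALIBRATION_TRUTH
    n_levels = opt.get("n_levels", 10)
    sweeps = {
        "sigma_act": opt.get("sigma_act_grid", [1.0, 1.5, 2.0]),
        "sigma_conf": opt.get("sigma_conf_grid", [0.6, 1.0, 1.6]),
        "rho": opt.get("rho_grid", [0.3, 0.6, 0.9]),
    }
    frames = []
    for k, (pname, grid) in enumerate(sweeps.items()):
        for v in grid:
            belief = BeliefParams.from_generative(truth, "second_order").with_(
                **{pname: float(v)})
            t = simulate_trials(truth, truth.theta, spec.n_trials, belief,
                                spec.seed + 100 * k + int(round(v * 1000)) % 97)
            cal = calibration_curve(t, n_levels)
            cal.insert(0, "believed_value", float(v))
            cal.insert(0, "varied_param", pname)
            cal.insert(0, "matched", bool(abs(float(v) - getattr(truth, pname)) < 1e-12))
            frames.append(cal)
    return pd.concat(frames, ignore_index=True)


# -- dispatcher --------------------------------------------------------------

_RUNNERS = {
    "x_pattern": run_x_pattern,
    "error_surface": run_error_surface,
    "action_effect": run_action_effect,
    "roc_sweep": run_roc_sweep,
    "metad_sweep": run_metad_sweep,
    "miscalibration": run_miscalibration,
}


def run_experiment(spec: ExperimentSpec):
    """Run an experiment; returns a DataFrame or a dict of named DataFrames."""
    return _RUNNERS[spec.experiment_id](spec)
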