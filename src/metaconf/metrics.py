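"""Metacognition metrics: type 2 ROC, meta-d', calibration, error detection.

All metrics operate on trial tables produced by
:func:`metaconf.model_core.simulate_trials` (or read from CSV).  Continuous
confidence is first discretized into K ordered rating categories by a
:class:`RatingScheme`; rating counts indexed by (stimulus, response,
rating) feed the ROC and the meta-d' maximum-likelihood fit.

meta-d' expresses metacognitive sensitivity in units of type 1 d': it is
the d' a standard equal-variance signal-detection observer would need, with
its type 1 criterion held at the empirically estimated relative criterion,
to produce the observed response-conditional rating distributions.  An
ideal observer whose confidence derives from the same sample as its choice
has meta-d' = d' (ratio 1); independent confidence noise pushes the ratio
below 1, while a privileged confidence channel (second-order observers with
low sigma_conf and moderate rho) can push it above 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model_core import DataError, ParameterError

__all__ = [
    "RatingScheme",
    "Type2ROC",
    "MetaDFit",
    "discretize_confidence",
    "rating_counts_frame",
    "type2_roc",
    "fit_meta_d",
    "error_detection_rate",
    "calibration_curve",
    "bias_and_sensitivity",
]


@dataclass(frozen=True)
class RatingScheme:
    """Partition of [0, 1] into ordered rating categories.

    ``edges`` are the interior cut points (length ``n_bins - 1``), strictly
    increasing within (0, 1).  Bin k is [edge_{k-1}, edge_k) with the last
    bin closed at 1.
    """

    n_bins: int
    edges: tuple

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ParameterError("a rating scheme needs at least 2 bins")
        e = np.asarray(self.edges, dtype=float)
        if e.size != self.n_bins - 1:
            raise ParameterError("need n_bins - 1 interior edges")
        if np.any(e <= 0) or np.any(e >= 1) or not np.all(np.diff(e) > 0):
            raise ParameterError("edges must be strictly increasing within (0, 1)")
        object.__setattr__(self, "edges", tuple(float(x) for x in e))

    @classmethod
    def equal_width(cls, n_bins: int) -> "RatingScheme":
        return cls(n_bins, tuple(np.linspace(0, 1, n_bins + 1)[1:-1]))

    @classmethod
    def quantile(cls, n_bins: int, z) -> "RatingScheme":
        """Edges at empirical quantiles of ``z`` (near-equal bin counts).

        Degenerate quantiles (ties) are nudged apart to keep the edges
        strictly increasing.
        """
        z = np.asarray(z, dtype=float)
        q = np.quantile(z, np.linspace(0, 1, n_bins + 1)[1:-1])
        q = np.clip(q, 1e-9, 1 - 1e-9)
        for i in range(1, q.size):
            if q[i] <= q[i - 1]:
                q[i] = np.nextafter(q[i - 1], 1.0)
        return cls(n_bins, tuple(q))

    def assign(self, z) -> np.ndarray:
        """Rating category (0 .. n_bins-1) for each confidence value."""
        z = np.asarray(z, dtype=float)
        if np.any(np.isnan(z)):
            raise DataError("confidence values contain NaN")
        return np.searchsorted(np.asarray(self.edges), z, side="right")


@dataclass(frozen=True)
class Type2ROC:
    """Response-unconditional type 2 ROC curve and its trapezoidal area."""

    false_alarm_rates: np.ndarray  # P(z >= criterion | error), increasing
    hit_rates: np.ndarray          # P(z >= criterion | correct), increasing
    area: float


@dataclass(frozen=True)
class MetaDFit:
    """Result of the meta-d' maximum-likelihood fit."""

    d_prime: float
    c: float
    meta_d: float
    meta_c: float
    type2_criteria: tuple
    nll: float

    @property
    def ratio(self) -> float:
        """meta-d'/d'; NaN when d' is (numerically) zero."""
        if abs(self.d_prime) < 1e-9:
            return float("nan")
        return self.meta_d / self.d_prime


# -- discretization ----------------------------------------------------------

def discretize_confidence(trials: pd.DataFrame, scheme: RatingScheme) -> np.ndarray:
    """Rating counts indexed by (stimulus, response, rating).

    Axis 0 is the world state (0: d=-1, 1: d=+1), axis 1 the response
    (0: a=-1, 1: a=+1), axis 2 the rating category.  Counts sum to the
    number of trials.
    """
    z = trials["z_post"].to_numpy(dtype=float)
    missing = np.nonzero(np.isnan(z))[0]
    if missing.size:
        raise DataError(f"z_post missing at rows {missing[:10].tolist()}")
    ratings = scheme.assign(z)
    counts = np.zeros((2, 2, scheme.n_bins), dtype=int)
    s_idx = (trials["d"].to_numpy() > 0).astype(int)
    r_idx = (trials["a"].to_numpy() > 0).astype(int)
    np.add.at(counts, (s_idx, r_idx, ratings), 1)
    return counts


def rating_counts_frame(counts: np.ndarray) -> pd.DataFrame:
    """Tidy ``stimulus,response,rating,count`` view of a counts array."""
    rows = []
    for si, s in enumerate((-1, 1)):
        for ri, r in enumerate((-1, 1)):
            for k in range(counts.shape[2]):
                rows.append((s, r, k, int(counts[si, ri, k])))
    return pd.DataFrame(rows, columns=["stimulus", "response", "rating", "count"])


# -- type 2 ROC --------------------------------------------------------------

def type2_roc(trials: pd.DataFrame, scheme: RatingScheme) -> Type2ROC:
    """Type 2 ROC: confidence as a classifier of correct vs incorrect trials.

    Sweeping the rating criterion, plots P(rating >= k | correct) against
    P(rating >= k | error); the area (trapezoid) is 0.5 for confidence
    unrelated to accuracy and 1 for perfect separation.
    """
    correct = trials["correct"].to_numpy(dtype=bool)
    n_corr, n_err = int(correct.sum()), int((~correct).sum())
    if n_corr == 0 or n_err == 0:
        raise DataError("type 2 ROC needs both correct and error trials")
    ratings = scheme.assign(trials["z_post"].to_numpy(dtype=float))
    hit, fa = [0.0], [0.0]
    for k in range(scheme.n_bins - 1, -1, -1):
        above = ratings >= k
        hit.append((above & correct).sum() / n_corr)
        fa.append((above & ~correct).sum() / n_err)
    fa_arr, hit_arr = np.asarray(fa), np.asarray(hit)
    area = float(np.trapezoid(hit_arr, fa_arr))
    return Type2ROC(fa_arr, hit_arr, area)


# -- meta-d' -----------------------------------------------------------------

def _norminv(p: float) -> float:
    return float(stats.norm.ppf(p))


def _type2_logprobs(meta_d, meta_c, cm, cp, K):
    """log P(rating k | stim s, resp r) under the meta-SDT model.

    cm: criteria below meta_c (descending), cp: above (ascending), each
    length K-1.  Returns array (2 stim, 2 resp, K).
    """
    mus = np.array([-meta_d / 2.0, meta_d / 2.0])
    out = np.full((2, 2, K), -np.inf)
    lo_bounds = np.concatenate(([-np.inf], cm[::-1], [meta_c]))  # ascending
    hi_bounds = np.concatenate(([meta_c], cp, [np.inf]))
    for si, mu in enumerate(mus):
        # response -1: x <= meta_c; rating 0 nearest the criterion
        p_resp_m = stats.norm.cdf(meta_c - mu)
        p_resp_p = 1.0 - p_resp_m
        for k in range(K):
            lo, hi = lo_bounds[K - 1 - k], lo_bounds[K - k]
            p = stats.norm.cdf(hi - mu) - stats.norm.cdf(lo - mu)
            out[si, 0, k] = math.log(max(p / max(p_resp_m, 1e-300), 1e-300))
            lo2, hi2 = hi_bounds[k], hi_bounds[k + 1]
            p2 = stats.norm.cdf(hi2 - mu) - stats.norm.cdf(lo2 - mu)
            out[si, 1, k] = math.log(max(p2 / max(p_resp_p, 1e-300), 1e-300))
    return out


def fit_meta_d(counts: np.ndarray, padding: float | None = None) -> MetaDFit:
    """Maximum-likelihood meta-d' from (stimulus, response, rating) counts.

    The type 1 criterion of the meta observer is fixed at the empirical
    relative criterion (meta_c = meta_d * c / d'), and meta-d' plus the
    2(K-1) type 2 criteria are fit by bounded quasi-Newton on the
    response-conditional rating likelihood.  Every cell is padded by
    ``padding`` (default 1/(2K)) before the fit to avoid zero cells.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[:2] != (2, 2) or counts.ndim != 3:
        raise ParameterError("counts must have shape (2, 2, K)")
    K = counts.shape[2]
    if padding is None:
        padding = 1.0 / (2 * K)
    padded = counts + padding
    if padded.sum() <= 0:
        raise DataError("degenerate rating counts: all cells zero after padding")

    # type 1 estimates from the padded marginals
    hr = padded[1, 1].sum() / padded[1].sum()
    far = padded[0, 1].sum() / padded[0].sum()
    d_prime = _norminv(hr) - _norminv(far)
    c = -0.5 * (_norminv(hr) + _norminv(far))
    c_rel = c / d_prime if abs(d_prime) > 1e-9 else 0.0

    def unpack(x):
        meta_d = x[0]
        dm = np.exp(x[1:K])
        dp = np.exp(x[K:])
        meta_c = meta_d * c_rel
        cm = meta_c - np.cumsum(dm)   # descending, below meta_c
        cp = meta_c + np.cumsum(dp)   # ascending, above meta_c
        return meta_d, meta_c, cm, cp

    def nll(x):
        meta_d, meta_c, cm, cp = unpack(x)
        lp = _type2_logprobs(meta_d, meta_c, cm, cp, K)
        return -float(np.sum(padded * lp))

    x0 = np.concatenate(([d_prime], np.full(2 * (K - 1), math.log(0.5))))
    bounds = [(-10.0, 10.0)] + [(-10.0, 2.5)] * (2 * (K - 1))
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500})
    if not res.success:  # one restart from a flatter criterion layout
        x1 = np.concatenate(([0.5 * d_prime], np.full(2 * (K - 1), math.log(0.25))))
        res2 = optimize.minimize(nll, x1, method="L-BFGS-B", bounds=bounds,
                                 options={"ftol": 1e-10, "gtol": 1e-8,
                                          "maxiter": 1000})
        if res2.fun < res.fun:
            res = res2
        if not res.success and not np.isfinite(res.fun):
            raise RuntimeError(f"meta-d' optimizer failed: {res.message}")
    meta_d, meta_c, cm, cp = unpack(res.x)
    crits = tuple(np.concatenate((cm[::-1], cp)))
    return MetaDFit(float(d_prime), float(c), float(meta_d), float(meta_c),
                    crits, float(res.fun))


# -- simple summary metrics --------------------------------------------------

def error_detection_rate(trials: pd.DataFrame) -> float:
    """Fraction of error trials reported with confidence below 0.5."""
    errors = trials.loc[~trials["correct"].astype(bool)]
    if len(errors) == 0:
        raise DataError("error-detection rate undefined: no error trials")
    return float((errors["z_post"] < 0.5).mean())


def calibration_curve(trials: pd.DataFrame, n_levels: int = 10) -> pd.DataFrame:
    """Proportion correct conditioned on equal-width confidence levels.

    Returns one row per level with the level midpoint, mean confidence,
    accuracy and trial count; empty levels have count 0 and NaN summaries.
    A well-calibrated observer's accuracy tracks the identity line.
    """
    if n_levels < 2:
        raise ParameterError("need at least 2 confidence levels")
    z = trials["z_post"].to_numpy(dtype=float)
    correct = trials["correct"].to_numpy(dtype=bool)
    level = np.clip((z * n_levels).astype(int), 0, n_levels - 1)
    rows = []
    for k in range(n_levels):
        sel = level == k
        cnt = int(sel.sum())
        rows.append({
            "level": k,
            "midpoint": (k + 0.5) / n_levels,
            "mean_confidence": float(z[sel].mean()) if cnt else float("nan"),
            "accuracy": float(correct[sel].mean()) if cnt else float("nan"),
            "count": cnt,
        })
    return pd.DataFrame(rows)


def bias_and_sensitivity(trials: pd.DataFrame, column: str = "z_post"):
    """Accuracy-balanced confidence level and the correct-error confidence gap.

    Bias is the unweighted mean of the class-conditional mean confidences,
    (E[z | correct] + E[z | error]) / 2, so it measures overall confidence
    level independently of the correct/error mix and of discriminative
    power; the raw grand mean of a calibrated observer is pinned to task
    accuracy and so cannot register action-induced shifts.  Sensitivity is
    the gap E[z | correct] - E[z | error] between the same two class means.
    """
    z = trials[column].to_numpy(dtype=float)
    correct = trials["correct"].to_numpy(dtype=bool)
    if correct.all() or not correct.any():
        raise DataError(
            "bias/sensitivity undefined: need both correct and error trials")
    m_corr = float(z[correct].mean())
    m_err = float(z[~correct].mean())
    return 0.5 * (m_corr + m_err), m_corr - m_err
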