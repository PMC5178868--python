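# Methods

This note records the models implemented in `metaconf`, the estimation and
numerical choices behind them, what the simulator does and does not
emulate, and the design decisions taken where more than one reasonable
construction existed.

## Generative model

A trial is a draw of a world state *d* ∈ {−1, +1} with P(*d* = +1) = 0.5
(fixed; asymmetric priors are out of scope), a stimulus strength
θ ∈ [0, 1] (fixed, or drawn from a discrete `ThetaPrior`), and a pair of
internal samples

(X_act, X_conf) ~ N([dθ, dθ], Σ),
Σ = [[σ_act², ρσ_actσ_conf], [ρσ_actσ_conf, σ_conf²]].

The pair is constructed from two standard-normal streams as
X_act = dθ + σ_act z₁ and X_conf = dθ + σ_conf(ρz₁ + √(1−ρ²) z₂), which
realises Σ exactly for all |ρ| ≤ 1 and lets experiments share the base
noise (z₁, z₂) across model variants so cross-model contrasts are paired.
The response is a = +1 iff X_act > 0; the tie at exactly zero maps to −1
(a measure-zero choice with no simulation impact). Task accuracy is
Φ(θ/σ_act) analytically.

Model-specific internal states in the simulator:

* first-order: one sample X ~ N(dθ, σ_act²); X_conf = X_act = X.
* postdecisional: X_act ~ N(dθ, σ_act²) plus an independent
  X_new ~ N(dθ, σ_act²); X_conf = X_act + X_new ~ N(2dθ, 2σ_act²).
* second-order: the bivariate draw above.

## Confidence computations

Confidence is z = P(a = d | evidence), computed with the observer's
*believed* parameters (a `BeliefParams`, which may deviate from the
generative values) and, when the believed θ is uncertain, with likelihoods
marginalized over a discrete θ prior.

* First-order: z = P(d = a | X_conf) with the N(dθ, σ_act²) likelihood.
  For a fixed θ this is logistic(2aθX_conf/σ²); since the action is the
  sign of the same sample, z ≥ 0.5 always (no error detection).
* Postdecisional: the same posterior under the summed-evidence likelihood
  N(2dθ, 2σ²); z < 0.5 occurs when the post-decision sample overturns the
  initial evidence.
* Second-order: the observer scores each world state by the confidence
  likelihood times the probability its own action would have occurred
  under that state, derived from the conditional distribution of X_act
  given X_conf:

  P(d | X_conf, a, Σ) ∝ N(X_conf; dθ, σ_conf²) · Φ(a μ_c(d)/σ_c),
  μ_c(d) = dθ + ρ(σ_act/σ_conf)(X_conf − dθ), σ_c = σ_act√(1−ρ²).

  The closed form was derived by bivariate-normal conditioning and is
  validated in the test suite against a brute-force oracle
  (`mc_oracle_confidence`) that simulates the true generative process and
  conditions on a narrow X_conf window and the action. With ρ = 1 and
  σ_act = σ_conf the action term is the same step function for both world
  states and the model collapses to the first-order posterior.

Numerical choices: all likelihoods are evaluated in log space
(`norm.logpdf`, `norm.logcdf`) and combined with log-sum-exp, so samples
beyond ±8 SD do not underflow. The degenerate |ρ| = 1 case (σ_c = 0) is
handled by the analytic limit of Φ: 1, 0, or ½ by the sign of μ_c, never
by dividing by zero.

A note on symmetries: z(x, a) = z(−x, −a) holds for all three models. The
complement z(x, +1) + z(x, −1) = 1 holds for the first-order and
postdecisional models, whose posteriors do not condition on the action; it
cannot hold for the second-order model, where the two conditionings refer
to different data (at x = 0, ρ = 0 both values equal Φ(θ/σ_act)).

## Pre-choice ("rate-choose") confidence

Two pre-choice quantities are exposed, and the distinction matters:

* `second_order_confidence_prechoice` — the evidence-only posterior
  P(d = sign(X_conf) | X_conf): confidence in the hypothetical response
  consistent with the confidence sample. Always ≥ 0.5.
* `second_order_predicted_confidence` — the prediction
  P(a = d | X_conf) = Σ_d P(d|X_conf) P(a = d | d, X_conf): the
  probability that the *upcoming* response will be correct, marginalizing
  the second-order posterior over the not-yet-taken action.

The simulator and the action-effect experiment use the predicted form for
the rate-choose condition, because it is the coherent report for an
observer asked "how confident are you that your response will be correct?"
before responding: the observer knows its own action system's average
reliability, so even an uninformative sample yields confidence near the
expected accuracy. This choice is what makes the choose-rate/rate-choose
contrast behave lawfully across the whole parameter range: conditioning on
the actual action lowers the balanced confidence level and raises the
correct−error confidence gap at every (σ_conf, ρ) setting tested, with
both effects vanishing in the first-order limit, where the action is a
deterministic function of the sample and both pre-choice quantities
coincide with the post-choice value trial by trial. The evidence-only
variant instead reverses the bias effect once σ_conf > σ_act (the action
term then dominates post-choice confidence), so it is kept as an
explicitly named alternative rather than the simulation default.

## Metacognition metrics

**Rating schemes.** Continuous z is discretized into K ordered categories;
bins are half-open [edge_i, edge_{i+1}) with the top bin closed at 1. The
default for fitting is K = 4 bins at empirical quantiles of z (avoids
empty cells in the likelihood); equal-width bins are available.

**Type 2 ROC.** Sweeping the rating criterion, P(rating ≥ k | correct) is
plotted against P(rating ≥ k | error); the area is trapezoidal. With
quantile-based ratings the area is invariant to strictly monotone
transforms of z.

**meta-d′.** Maximum-likelihood fit of an equal-variance Gaussian SDT
observer to the response-conditional rating distributions. Type 1 d′ and
criterion c come from the padded response marginals; the meta observer's
type 1 criterion is fixed at the empirical relative criterion
(meta_c = meta_d · c/d′); the free parameters are meta_d and 2(K−1)
type 2 criteria, parameterized as log-increments away from meta_c to
enforce ordering, optimized by L-BFGS-B (ftol 1e-10, one restart from a
flatter criterion layout on non-convergence). Every cell is padded by
1/(2K) before the fit. d′ ≈ 0 reports the ratio as NaN rather than
infinity. Parameter recovery is verified in the tests: first-order data
give ratio = 1 within sampling error and recover the analytic d′ = 2θ/σ;
shuffling confidence across trials drives meta-d′ to 0.

**Bias and sensitivity.** Sensitivity is E[z | correct] − E[z | error].
Bias is the *accuracy-balanced* confidence level
(E[z | correct] + E[z | error])/2 rather than the grand mean: a calibrated
observer's grand mean equals task accuracy by the tower property, so it
cannot register action-induced confidence shifts, whereas the balanced
level measures overall confidence independently of the correct/error mix
and of discriminative power. Both are undefined when only one accuracy
class is present.

**Calibration.** Proportion correct conditioned on equal-width confidence
levels (default 10). Calibration identity is checked as accuracy vs the
mean confidence within each level, not the level midpoint: the posterior
mean inside a 0.1-wide bin is not its midpoint (top bin ≈ 0.97 vs 0.95),
and a perfectly calibrated observer would "fail" a midpoint comparison at
large n.

**Error detection.** Fraction of error trials with z < 0.5. It is exactly
0 for the first-order model, decreases as σ_conf grows, and — when
σ_conf ≥ σ_act — decreases to ~0 as ρ → 1 (the first-order reduction).
When σ_conf < σ_act the confidence channel outranks the decision channel
and detection survives high ρ (at σ_conf = 0.5, σ_act = 1 the rate is
~0.95 at ρ = 0 and ~0.98 at ρ = 0.995: with near-deterministic coupling
and a sharp confidence channel, errors become logically deducible). The
monotone-in-ρ law is therefore asserted only on the σ_conf ≥ σ_act half
of the surface.

## Experiments

Each experiment is a pure function of (`ExperimentSpec`, seed); re-running
reproduces identical tables. Defaults, chosen once as the study
conditions:

* X-pattern: θ drawn per trial from a uniform 20-point grid on [0, 1],
  which the observer does not know, so its confidence marginalizes over
  the same grid; internal-state profiles use 25 equal-count X_conf bins;
  all three models consume shared noise.
* Error surface: σ_act = 1, θ = 1 (≈84% correct everywhere), grids over
  σ_conf and ρ.
* Action effect: σ_act = 1, θ = 1; σ_conf sweep at ρ = 0.6 and ρ sweep at
  σ_conf = 1; pre- and post-choice confidence computed on identical
  trials.
* meta-d′ sweep: ρ = 0.5, θ = 1, deterministic grid over
  σ_act, σ_conf ∈ [0.25, 3] (a deterministic grid replaces random
  parameter sampling for reproducible coverage), one dataset per cell,
  K = 4 quantile ratings; failed fits reported as NaN.
* Miscalibration: generative parameters fixed at σ_act = 1.5,
  σ_conf = 1, ρ = 0.6; one believed parameter varied per sweep; 10
  equal-width confidence levels.

Per-condition trial counts default to 1e5 (4e5–1e6 where binomial
precision matters, e.g. calibration identity); the test suite uses
2e4–3e5 per condition, sized by standard-error arithmetic so each
directional assertion has comfortable margin.

## What the simulator does and does not emulate

The generator realises exactly the stationary, equal-variance,
bivariate-Gaussian world of the models: flat prior on two world states,
Gaussian evidence with known (or believed) moments, a neutral decision
criterion, and noiseless report of the computed posterior. Passing tests
therefore show internal consistency of the inference and estimation
machinery and reproduce the models' qualitative laws; they do not show
that real observers satisfy those assumptions. Real data involve
criterion drift and lapses, non-Gaussian or serially dependent evidence,
temporal accumulation and response times, discretized and biased rating
scales, and learning of the hyperparameters — all outside scope here
(`Non-goals`: sequential dynamics, response times, non-Gaussian noise,
more than two world states, hierarchical meta-d′).

## Known limitations

* The meta-d′ fit assumes the standard equal-variance type 1 model and a
  fixed relative criterion; criterion variability corrections are not
  implemented.
* The predicted pre-choice confidence can itself fall below 0.5 when
  σ_conf ≪ σ_act (the observer foresees that its action system will
  likely err) — a real feature of the inference, but one that the
  evidence-only pre-choice variant cannot express.
* θ marginalization uses a discrete grid prior; a continuous prior would
  require quadrature and is not needed for the grid-based experiments.
* Figure-level experiments are qualitative-shape reproductions; exact
  per-condition trial counts and θ grids of the original simulations are
  not public, so point values are not targeted beyond the anchors checked
  in the acceptance tests.
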