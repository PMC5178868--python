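# metaconf

Bayesian observer models of decision confidence and metacognition for
two-alternative forced-choice tasks, with a trial simulator and a metrics
suite (type 2 ROC, meta-d′, calibration, error detection).

## Who this is for

Researchers in computational cognitive science and psychophysics who want
to simulate how confidence reports arise from noisy internal evidence, and
to understand dissociations between task performance and metacognition:
error detection, hyper- and hypo-metacognitive sensitivity
(meta-d′/d′ ≷ 1), effects of one's own actions on confidence, and
systematic over-/underconfidence.

## The models

On each trial a world state *d* ∈ {−1, +1} generates a pair of internal
samples — the decision variable *X*<sub>act</sub> and the confidence
variable *X*<sub>conf</sub> — from a bivariate Gaussian with mean
*dθ* on both axes (*θ* ∈ [0, 1] is stimulus strength) and covariance

```
Σ = [ σ_act²            ρ σ_act σ_conf ]
    [ ρ σ_act σ_conf    σ_conf²        ]
```

The observer responds *a* = +1 iff *X*<sub>act</sub> > 0. Confidence is
the posterior probability the response was correct,
*z* = P(*a* = *d* | evidence), under one of three model classes:

* **first-order** — the confidence variable *is* the decision variable;
  *z* = P(*d* = *a* | *X*<sub>conf</sub>) with
  *X*<sub>conf</sub> ~ N(*dθ*, σ²). Confidence never falls below 0.5: the
  observer cannot represent having erred.
* **postdecisional** — the confidence variable is the decision variable
  plus one further independent evidence sample, so
  *X*<sub>conf</sub> ~ N(2*dθ*, 2σ²). Confidence below 0.5 (error
  detection) becomes possible.
* **second-order** — decision and confidence variables are distinct,
  correlated samples, and the observer additionally treats its own action
  as data, inverting the generative model:

  P(*d* | *X*<sub>conf</sub>, *a*, Σ) ∝
  N(*X*<sub>conf</sub>; *dθ*, σ<sub>conf</sub>²) ·
  Φ(*a* μ<sub>c</sub>(*d*) / σ<sub>c</sub>),

  with μ<sub>c</sub>(*d*) = *dθ* + ρ(σ<sub>act</sub>/σ<sub>conf</sub>)(*X*<sub>conf</sub> − *dθ*)
  and σ<sub>c</sub> = σ<sub>act</sub>√(1 − ρ²). With ρ = 1 and
  σ<sub>act</sub> = σ<sub>conf</sub> it reduces exactly to the first-order
  model.

The observer's *believed* parameters (hyperparameters) may differ from the
generative ones, which produces systematic miscalibration; a believed θ may
also be a discrete prior that confidence marginalizes over.

Metacognitive sensitivity is quantified by the type 2 ROC area and by
meta-d′ — the type 1 d′ an equal-variance signal-detection observer would
need, with its type 1 criterion held at the empirical relative criterion,
to reproduce the observed response-conditional rating distributions. An
ideal first-order observer has meta-d′/d′ = 1; a privileged confidence
channel (σ<sub>conf</sub> < σ<sub>act</sub>, moderate ρ) pushes the ratio
above 1 alongside the emergence of error detection.

## Worked example

Evaluate second-order confidence at exactly equivocal evidence
(*X*<sub>conf</sub> = 0) after a response, at the canonical parameters
σ<sub>act</sub> = 1, σ<sub>conf</sub> = 1, ρ = 0.6, θ = 1:

```bash
$ metaconf confidence --model second_order --x-conf 0 --action 1 \
      --sigma-act 1 --sigma-conf 1 --rho 0.6 --theta 1
0.69146246
```

Even though the sample says nothing about the world, the observer knows
its action system is usually right, so confidence sits at
Φ(0.5)/(Φ(0.5)+Φ(−0.5)) ≈ 0.69, not 0.5.

Simulate 100,000 trials of the same observer and score its metacognition:

```bash
$ metaconf simulate --model second_order --sigma-act 1 --sigma-conf 1 \
      --rho 0.6 --theta 1 --n 100000 --seed 7 -o demo.csv
$ metaconf metrics --in demo.csv --bins 4
type2_area            0.812848   (n=100000)
d_prime               1.997681   (n=100000)
meta_d                2.310057   (n=100000)
meta_d_ratio          1.156369   (n=100000)
accuracy              0.841070   (n=100000)
error_detection_rate  0.297427   (n=15893)
```

Accuracy is Φ(θ/σ<sub>act</sub>) = Φ(1) ≈ 0.84 and the fitted d′ ≈ 2
matches the analytic 2θ/σ<sub>act</sub>. Because the confidence variable
is only partly coupled to the decision variable (ρ = 0.6), the observer
recognises about 30% of its errors (confidence < 0.5), and its meta-d′
exceeds d′ — metacognition "better" than performance, which no purely
first-order observer can produce (re-run with `--model first_order` to get
a ratio ≈ 1 and an error-detection rate of exactly 0).

The same functionality is available as a library
(`metaconf.simulate_trials`, `metaconf.second_order_confidence`,
`metaconf.fit_meta_d`, `metaconf.run_experiment`, ...); see
`docs/methods.md` for the model and estimation details.

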