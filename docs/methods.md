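# Methods

## Clinical setting and model

After hysteroscopic adhesiolysis for intrauterine adhesions (IUA), the
clinically useful quantity is each patient's prospect of natural conception:
it decides whether to wait or to move to assisted reproductive technology
(ART).  `iuasurv` models this as a proportional-hazards problem over
second-look hysteroscopy images.  A convolutional backbone maps an image to
pooled features; a small Cox regression head maps features to a single
scalar log-hazard h_θ(x) of conception.  The classical linear model
h_β(x) = βᵀx is the special case with an identity backbone and a
no-hidden-layer head, and is implemented independently (Newton–Raphson) as
the analytic oracle and the hazard-ratio engine.

The fitting target is the Cox partial likelihood with Breslow handling of
tied event times,

    L(θ) = ∏_{i: E_i=1}  exp h_θ(x_i) / Σ_{j ∈ R(T_i)} exp h_θ(x_j),

where T_i is months from surgery to conception or censoring, E_i = 1 for an
ongoing pregnancy (fetal heartbeat beyond 12 gestational weeks), and R(t)
is the risk set of patients still unconceived and uncensored just before t.
The training loss is the per-event negative log partial likelihood plus an
L2 penalty,

    l(θ) = −(1/N_{E=1}) Σ_{i:E_i=1} [ h_θ(x_i) − log Σ_{j∈R(T_i)} e^{h_θ(x_j)} ] + λ‖θ‖²₂ .

Key properties relied on throughout: the loss is invariant to adding a
constant to all scores (only score *differences* are identified), and with
a linear head it is convex with the Newton fit as its unique optimum up to
that shift.

### Assumptions

- Proportional hazards: the image effect multiplies a common baseline
  hazard and does not change over time.
- Independent (non-informative) right censoring, conditional on the image.
- One latent prognosis per patient; multiple views of the same patient are
  exchangeable readouts of it (aggregated by the mean of per-image
  log-hazards; max pooling is available).

## From scores to probabilities

Scores become time-resolved conception probabilities through the Breslow
cumulative baseline hazard, Ĥ₀(t) = Σ_{t_k ≤ t} d_k / Σ_{j∈R(t_k)} e^{s_j},
evaluated as a right-continuous step function that is 0 before the first
event time:

    P(conceive by t | x) = 1 − exp(−Ĥ₀(t) · e^{h_θ(x)}).

This is monotone in both the horizon and the score and lies in [0, 1] by
construction.  With all scores zero, exp(−Ĥ₀) is the Nelson–Aalen survival
curve and agrees with the Kaplan–Meier product-limit estimate to O(1/n);
the test suite checks the discrepancy empirically (< 0.02 at n = 500).

## Network architecture and training

The survival head follows the reported grid-search optimum: two hidden
layers of 8 units, SELU activations, batch normalization, dropout 0.5
inside the head and 0.2 after the pooled backbone features, a single linear
output node.  The default training configuration is likewise the reported
optimum (learning rate 0.154, weight decay λ = 0.00567, momentum 0.887,
Nadam, batch 16); SGD with Nesterov momentum, gradient clipping by global
norm and a multiplicative learning-rate schedule are provided.  That
learning rate is appropriate for fine-tuning a small head on pooled
transfer-learning features; the desk-scale CNN experiments in this package
train the whole `tiny_test` backbone from scratch and therefore pass their
own configuration (learning rate 0.01, decay 0.96/epoch, λ = 1e-4, 35
epochs), chosen once as ordinary settings for a three-layer CNN and not
revisited.

Minibatch Cox training forms risk sets *within* each minibatch: a batch is
sorted by follow-up time and contributes the Breslow partial likelihood
over its own members.  This is the only consistent reading of Cox training
with small batches; a batch that contains no event carries no likelihood
information and is skipped (counted in the history).  With batch size ≥
cohort size the objective equals the full-cohort loss exactly, which the
suite asserts, and a full-batch mode serves for head fine-tuning.  All
randomness (initialization, shuffling, dropout) derives from one seed;
repeated runs are bit-identical.

Because no deep-learning framework is assumed, the layer engine
(convolution via im2col, batch norm, SELU, inverted dropout, max/global
pooling, dense, Nadam, Nesterov SGD) is implemented in NumPy inside the
package with exact reverse-mode gradients, verified against central finite
differences in the tests.

### The four published backbones

InceptionV3, ResNet50, InceptionResNetV2 and VGG19 participate as
*architecture tapes*: declarative walks of each headless architecture graph
that track channel and spatial dimensions and record every parameterized
layer.  Parameter totals (trainable weights plus batch-norm moving
statistics; scaled BN = 4/channel for ResNet50, scale-free BN = 3/channel
for the Inception family) and forward-pass FLOPs are exact arithmetic over
the tape.  The computed totals reproduce the published per-architecture
parameter counts exactly.  FLOPs use the multiply-accumulate = 2 convention
and record it in the `ComplexityReport`; published FLOP figures depend on
an unstated convention, so agreement there is not claimed.  The 336 × 336
input overrides the architectures' canonical sizes, which global pooling
makes valid; parameter counts are unaffected and FLOPs scale accordingly.

## Evaluation

- **Harrell's c-index**: a pair is usable when the earlier time is an event
  time (including an event tied with a censoring); concordant when the
  earlier event carries the higher score (higher score = higher conception
  hazard = earlier conception); score ties credit 0.5.  The implementation
  is exact pair counting, verified against O(n²) brute-force enumeration
  and against an independent library implementation.
- **Time-dependent AUC**: Uno-style cumulative-case/dynamic-control AUC at
  a horizon with inverse-probability-of-censoring weights from the
  Kaplan–Meier estimate of the censoring distribution (cases weighted
  1/Ĝ(T_i⁻), controls 1/Ĝ(t); patients censored before the horizon get
  zero weight, no imputation).  With no censoring before the horizon it
  reduces *exactly* to the Mann–Whitney AUC of the binary label T ≤ t, and
  it matches an independent IPCW implementation to 1e-6 on censored data.
- **Calibration**: predictions at a horizon are quantile-binned (5 bins);
  the observed frequency is 1 − KM survival at the horizon within the bin,
  with a binomial-style CI.  A bin with no events and no follow-up to the
  horizon is flagged unavailable rather than imputed.
- **Comparisons**: paired patient-level bootstrap of the c-index or AUC
  difference, two-sided p from the normal approximation of the bootstrap
  distribution (B = 1000 default, seeded).  Identical scores give p = 1 by
  the zero-difference/zero-variance convention.
- Confidence intervals everywhere are seeded patient-level bootstrap
  percentiles, clipped to bracket the point estimate.

## Grad-CAM

For the scalar survival output, channel weights are the spatial means of
∂(output)/∂A at a convolutional layer (default: the last), the weighted
activation sum is rectified, max-normalized per image and bilinearly
upsampled.  The model outputs conception hazard while clinicians read the
maps as *subfertility risk*, so the default negates the output before
backpropagation (red = risk factor for subfertility, i.e. adhesion tissue);
`sign="hazard"` gives the raw direction.  A constant-output model yields an
all-zero map with a warning.  Heatmaps are invariant to constant shifts of
the model output.

## ART-benefit stratification

Patients are split at a predicted 1-year natural-conception probability of
0.5 (boundary values go to the low-probability group); clinical comparator
stratifications use AFS ≥ 5, CSGE ≥ 18 and endometrial thickness ≥ 7 mm.
Within each stratum the ART benefit is the Cox hazard ratio of conception
for ART users vs non-users, exp(β̂), with Wald 95% CI and two-sided p.

Two conventions are implemented because ART typically begins months after
surgery.  The default enters ART as a baseline binary covariate with time
from surgery — the plain reading of a stratified HR table.  The
time-dependent option delays the ART arm's risk-set entry to the ART start
month (left truncation).  On the package's own generator, where ART reaches
only patients still unconceived at month 12, the baseline-covariate
estimate is biased *below* 1 by that selection (immortal-time artefact)
even when the true multiplier is 3; the time-dependent estimator recovers
the generating hazard ratios, so the generator-truth recovery tests and the
acceptance script use it.  Neither convention is claimed to be the one
behind any published table.

Censoring semantics are likewise configurable at cohort load: by default
ART users' follow-up is kept as recorded; a switch right-censors them at
the ART start month for a natural-conception-only model.

## Synthetic cohort generator

The generator is the package's study bench: schematic second-look
hysteroscopy views (a pale cavity silhouette on a dark endoscopic
background with an illumination gradient and Gaussian noise; two cornua
views with an ostium disc) whose adhesion-like dark bands grow in number
and thickness with a latent severity ∈ [0, 1], plus survival outcomes from

    h_i = baseline_rate · exp(beta_severity · (severity_i − 0.5)),

exponential event times (a Weibull shape parameter is exposed for
robustness checks), administrative censoring at 48 months, exponential loss
to follow-up, and an optional ART mechanism: patients still unconceived at
month 12 receive ART with probability 0.5, after which their hazard is
multiplied by a stratum-specific ratio (default 3.0 where the true 1-year
conception probability is below 0.5, 1.0 above).  Severity is centered at
0.5 so `baseline_rate` (default 0.05/month ≈ two-thirds of patients
conceiving within follow-up) is the median patient's hazard.  A truth table
records severity, true log-hazard and counterfactual times, and every draw
descends from a single mandatory seed.

Default effect size is `beta_severity = −1.2` (hazard ratio ≈ 3.3 across
the severity range), a realistic prognostic gradient.  The *strong-signal*
condition used by the end-to-end learning and Grad-CAM experiments sets
`beta_severity = −6.0`: at n = 200 with three views per patient this puts
the 12-month discrimination ceiling of the generating law (AUC of the true
severity itself) around 0.85–0.95, leaving headroom for a small CNN to
clear 0.8 from pixels alone.  Both values were fixed as study conditions,
not tuned per run.

What the generator does *not* emulate: real endometrial texture, vascular
patterns, specular reflections, view-pose variability, inter-operator
differences, or the semantics of AFS/CSGE scoring (its clinical covariates
are noisy monotone proxies of severity).  Passing tests therefore
demonstrate that the pipeline learns and explains a visually encoded
prognostic factor under a known hazard law — not clinical-grade
performance on real hysteroscopy.

## Numerical choices

- Tied event times: Breslow approximation everywhere (likelihood, gradient,
  baseline hazard); Efron and exact corrections are out of scope.
- Newton–Raphson: start at β = 0, max 50 iterations, convergence when the
  log-likelihood change < 1e-9, step-halving on decrease, standard errors
  from the inverse observed information; runaway coefficients (|β| > 50)
  raise a divergence error (monotone likelihood / complete separation).
- Censoring-distribution KM resolves event/censoring ties with events
  first; IPCW case weights use Ĝ(T⁻).
- Batch norm: momentum 0.9, ε = 1e-5; inference uses moving statistics.
- Max-pool gradients split equally among tied maxima (determinism).
- Image preprocessing: bilinear resize to the square input size, scaling to
  [−1, 1]; clinical backbones reject inputs under 300 px a side.
- Risk-group boundary values go to the low-probability group.

## Problem sizes

Desk-scale experiment sizes, chosen once: end-to-end trainings use 200
patients × 3 views at 64 px with 35 epochs (three independent seeds);
oracle-equivalence and recovery simulations use n = 500; CI coverage uses
200 replicates of n = 300; calibration uses n = 1000; generator-honesty
checks use n = 2000 (tabular only).

## Known limitations

- The four published backbones are analytic tapes only; no pretrained
  weights ship with the package, so clinical-scale transfer learning is out
  of scope (the trainable path is the `tiny_test` CNN and the tabular
  head).
- The calibration bound of 0.05 per bin is tighter than the binomial noise
  of a 5-bin/1000-patient design (~0.035 SE per mid-range bin); see the
  test suite, where the large-n calibration check passes and the n = 1000
  check is reported as-is.
- Per-patient aggregation (mean of log-hazards) is a modelling choice, not
  an estimated quantity.
- No competing risks, time-varying covariates or frailty terms.
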