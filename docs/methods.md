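# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the open design decisions behind `disgaze`. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Dwell-time measurement model

Fixations are points (centroid x, y in screen pixels, origin top-left,
0-based) with durations in ms. AOI membership uses half-open rectangles
(left/top edge inclusive, right/bottom exclusive), stated once in
`gaze_metrics` and used everywhere; a fixation spanning an AOI boundary is
assigned by its centroid only, with no duration splitting. The default
geometry — 1280 × 1024 screen, 400 × 300 images, centres 640 px apart — puts
the left image at [120, 520) × [362, 662) and the right at [760, 1160) ×
[362, 662).

Dwell proportions are normalised by **total fixation time within the
trial**, not trial wall-clock, so disgust + neutral + non-stimulus always
partition 1 and the three-way split is well defined even on partially
tracked trials. Missingness is handled separately as
1 − valid_fraction, where valid_fraction = tracked time ÷ nominal trial
duration; a trial is dropped iff its missingness **strictly exceeds** 50 %
(a trial at exactly 50 % is retained). Trials with no fixation time at all
are flagged missing and always dropped.

The avoidance score is p(neutral) − p(disgust) ∈ [−1, 1]; positive values
mean gaze avoided the disgusting image.

## Reinforcement-learning model

Two-armed bandit, binary rewards. Associative values start at (0, 0), so
the first-trial softmax probability is exactly 0.5 for both arms — an exact
property, tested as such. Only the chosen arm's value is updated (the
standard convention for this delta rule). The dual-rate variant applies
η_win after wins and η_lose otherwise and reduces exactly to the single-rate
model when the two rates are equal.

**Fitting** is maximum likelihood — the simplest estimator consistent with
"parameters derived from a basic reinforcement-learning model" — by
multi-start local optimisation (L-BFGS-B, ftol 1e-10) on transformed
parameters: logit(η) (bounded to |x| ≤ 16) and log β, with β capped at 20
as an identifiability guard on 88 binary trials; fits at the cap are
flagged. Defaults: 20 starts, η starts uniform on [0, 1], β starts
log-uniform on [0.1, 20], plus a deterministic mid-range start. The dual
fit additionally starts from the best single-rate solution, which makes the
nesting inequality (dual NLL ≤ single NLL) hold by construction up to
optimiser tolerance. The likelihood recursion is guarded against exp
overflow (log1p/exp formulation, hard clamps at |x| = 700).

AIC = 2k + 2·NLL and BIC = k·ln(n) + 2·NLL with n = trial count; k = 2
(single) or 3 (dual).

Whether to fit per session or pooled is not dictated by the data layout;
the pipeline fits per participant × visit × task-run (pre-/post-
administration), which is what the pre/post drug comparison needs.

## Evidence machinery

Akaike weights are the two-model softmax of −AIC/2; the evidence ratio for
the null is ER₀ = w₀/w₁, which for two models collapses algebraically to
exp(½ (AIC₁ − AIC₀)) — this identity is used as a test oracle. The BIC
Bayes factor is BF₀₁ = exp(½ (BIC₁ − BIC₀)). Both are computed and stored
in natural-log space; the float-space values underflow/overflow gracefully
to 0/inf without ever producing NaN, and a formatter renders magnitudes far
beyond float range (e.g. `2.73e+347`) from the log value. Jeffreys-style
interpretation uses strict thresholds: ≤ 3 inconclusive, > 3 evidence,
> 10 strong, > 100 decisive. The strict boundary at 3 matters: a factor of
exactly 3 is *not* evidence. The 10/100 cut points follow the common
Jeffreys-scale convention, since only the 3 threshold is fixed by the
workflow this package implements.

## Mixed-model inference

Trial-level outcomes are fitted with `statsmodels` MixedLM (participant
random intercept) by **maximum likelihood, not REML**, because the
null-evidence workflow compares models that differ in fixed effects, and
REML likelihoods are not comparable across mean structures. AIC/BIC use
k = number of fixed effects + 2 variance parameters, n = observations.

Factor coding is sum-to-zero ±1 (disgust/domperidone/later-phase positive)
with the trial index z-scored, and the outcome z-scored when `standardize`
is set, so coefficients are standardized βs. Inference is Wald Z (normal
reference), not t with adjusted df; no Kenward–Roger/Satterthwaite
correction is applied. Dwell proportions are modelled on the raw proportion
scale.

Optimisation tries `lbfgs` first, then the gradient-free `nm`/`powell`
fallbacks, which are the methods that converge when the random-intercept
variance sits on the boundary (the singular case, common in the 2-obs-per-
participant post hoc difference models); a singular fit is retained with a
warning, while genuine non-convergence across all methods raises with
diagnostics.

Per-trial disgust-vs-neutral comparisons use a two-sided paired t-test
across participants (the simplest paired family; the choice is
configurable in principle but not exposed), with cells under 3 pairs or
with zero-variance nonzero differences flagged untestable rather than
assigned p = 1; an all-zero difference cell is a true p = 1. The
Holm–Bonferroni step-down is implemented directly from its definition
(reject the i-th smallest p while p ≤ α/(m − i + 1), stop at the first
failure) and is cross-checked against an independent library implementation
in the tests.

## Synthetic-data generator

The generator defines the study conditions: 25 participants, two
counterbalanced visits (placebo/domperidone), five preferential-looking
phases per visit with 24, 24, 10, 10, 10 trials, two 88-trial bandit runs
per visit, and 0–100 self-report ratings at four collection points.

**Gaze.** Each image's dwell share is generated on the logit scale —
grand mean (neutral default 1.5), stimulus effect on the disgust predictor
(default −1.5), participant intercept ~ N(0, 0.5²), independent trial noise
~ N(0, 0.8²), and an injectable drug × phase × stimulus interaction applied
only to domperidone-visit post-incentive trials — and mapped through a
half-scaled logistic, p = 0.5·sigmoid(lin), with non-stimulus dwell taking
the remainder. This mapping keeps every proportion in [0, 1] with the three
summing to 1, composes effects additively on the logit scale, and keeps the
disgust and neutral streams conditionally independent given the
participant, which is what makes the trial-level LMM's Wald test calibrate
at its nominal α (an earlier shared-denominator mapping was rejected for
inducing within-trial correlation and an inflated type-I rate; the
calibration is itself an acceptance check). The cost is a 0.5 ceiling per
image's expected share. Trial duration defaults to 15 s (configurable; only
the 24-trials-in-7-minutes block timing is fixed by the design, which
includes inter-trial intervals). Per-trial missing fractions are drawn from
Beta(2r, 2(1−r)) with mean r (default 0.05): most trials lose little
tracking, a small tail crosses the 50 % drop threshold, mimicking
occasional track loss.

When fixation output is requested, the target proportions are realised
exactly as fixation chunks (≤ 1.5 s) placed uniformly inside the
corresponding AOI (or the inter-image gap for non-stimulus time), scaled to
the trial's tracked time — so the dwell pipeline recovers the generated
proportions to machine precision. No saccade dynamics, no 1000-Hz gaze
samples, no spatial autocorrelation of fixations: passing tests show the
*accounting* from fixations to proportions is right, not that fixation
detection on raw data would be.

**Choices.** Agents draw η ~ U[0.1, 0.7] and β ~ U[1, 8] per participant,
reused across visits and runs — i.e. the generator injects **no** drug
effect on learning, which is exactly the null the evidence workflow is
expected to recover. Reversal points sit at ⌊k·n/(r+1)⌋ ± 2 trials of
uniform jitter, clipped to stay strictly increasing and interior; which arm
starts rich is a coin flip.

**Self-report.** Ratings on 0–100 (scale chosen here; anchors are not part
of the design), disgust mean 65 vs. neutral 10, rating sd 12, participant
sd 8, 12 items per category and phase, clipped to the scale.

**Reproducibility.** One RNG per participant, seeded from (seed,
participant id), so any participant subset reproduces exactly; identical
seed + config ⇒ byte-identical tables.

## Problem sizes used in the checks

Parameter recovery uses 200 agents (88 trials each, η ~ U[0.1, 0.9],
β ~ U[1, 10]) with a ≥ 0.5 Spearman threshold per parameter fixed in
advance of the main build from a pilot oracle run. Null-evidence
calibration uses 100 replicate studies and the win-proportion measure
(the workflow is identical for fitted parameters; win proportion needs no
per-replicate refitting). Type-I calibration of the triple-interaction test
uses 200 null studies of 25 participants, asserting the rejection count
inside a ±3.5 sd binomial band around the nominal 5 % (2–20 of 200). The
interaction-recovery check injects +0.7 logits at a fixed seed.

## Known limitations

- The Wald-Z/ML convention means p-values are mildly anticonservative for
  very small participant counts; the design here (≥ 25 × trial-level data)
  is comfortably inside its regime, and the calibration check guards it.
- The generator's logistic dwell model caps each image's expected dwell
  share at 0.5 and has no trial-order dynamics (no habituation trend), so
  trial effects are pure noise under the null.
- BIC Bayes factors inherit the unit-information-prior approximation; no
  prior-based Bayes factors are provided.
- Only two-model comparisons are supported, matching the model-vs-null
  workflow.
- Self-report and gaze streams are generated independently; real data
  correlate them.
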