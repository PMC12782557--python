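# Methods

This note documents the models, the synthetic-data generators, and the
numerical and design choices behind `pupilgain`.

## Ideal observer

The observer is a sequential Dirichlet-categorical learner. With prior
concentrations `α` and counts `n_k` after `j` observations, the belief is
`Dir(n_k + α_k)` and its mean is `(n_k + α_k)/(j + Σα)`. Conventions, fixed
throughout:

* **Surprise** uses the *pre-update* predictive probability of the observed
  event. **Entropy** and **information gain** use *post-update* quantities:
  entropy of the new posterior mean, and KL divergence from the old to the
  new posterior mean. The rationale is that at feedback time the trial's
  information has already been received, whereas surprise measures how
  unexpected the event was beforehand.
* Information gain is categorical KL between mean probability vectors, not
  KL between full Dirichlet densities. (Hierarchical or volatility-aware
  learners and density-level KL are out of scope.)
* All logarithms are base 2; units are bits.
* Probabilities are clipped at 1e-12 before logs. With positive `α` this
  guard never binds; it exists so degenerate inputs fail loudly rather than
  silently producing infinities.

The textbook predictive form `(n_k + α_k)/(j − 1 + K)` only normalizes when
`Σα = K`, so the implementation uses the general denominator `j − 1 + Σα`.
Priors built from probability vectors default to pseudo-count scaling
`α = K·P_o` (sum `K`), which recovers the textbook form exactly; a
`raw_probabilities` mode (`α = P_o`, sum 1) is available because the
original scaling convention for exposure-derived priors is ambiguous — the
two modes give the same posterior-mean *ordering* but different update
speeds.

**Exposure-derived prior.** For the letter-color task the prior is
estimated from the odd-ball stream as `P_o,k = (n_k + 1)/(N_reg + 36)` over
regular trials only; odd-ball trials neither count nor advance the
observer (their probabilities are not modelled). Note the package's mean
final probabilities under this count model (≈0.054/0.077/0.134 for the
three frequency conditions) are reproducible only in their ordering, which
is what the tests assert; the absolute values depend on the normalization
convention, for which no uniquely defensible choice exists.

## Task generators

* **Cue-target 2AFC** (default 200 trials): cues split exactly 50/50; within
  each cue the mapped orientation appears on exactly 80% of trials
  (exact-count composition, matching the "80% of the trials" design
  description); order shuffled per seed; two counterbalanced mappings. An
  i.i.d. Bernoulli variant is available by config.
* **Odd-ball exposure** (default 660 trials): 60 odd-balls (9% of 660 is
  59.4; 60 is the divisible default and configurable), 600 regular trials
  with six letters shown 100 times each. A letter with intended association
  frequency `f ∈ {0.2, 0.4, 0.8}` takes its associated color with
  probability `f`, otherwise a color drawn uniformly from all six shades —
  realizing `f + (1−f)/6` = 1/3, 1/2, 5/6 (the "33/50/84%" conditions) and
  `(1−f)/6` per unassociated color. Letter→color and letter→condition
  assignments are randomized per participant.
* **Letter-color 2AFC** (default 250 trials): half match trials uniform over
  the 6 associated pairs, half no-match uniform over the 30 unassociated
  pairs. The design description is internally inconsistent (a strict 1:1
  match ratio and equal frequency of all 36 pairs cannot both hold); the
  default honors the 1:1 ratio, and an `equal_36` composition is available.
* **Behavior**: the default policy is probability matching — the response
  frequency tracks the contingency, so accuracy within a frequency
  condition approximates the frequency itself (the empirically observed
  pattern on the cue-target task). A fixed-accuracy policy (default 0.8,
  matching letter-color performance) is used where matching is undefined.
  RTs are log-normal (median 0.7 s, σ = 0.3 log-units) with a +0.3
  log-shift on errors.

## Pupil synthesis

Traces are a mean level (5000 arbitrary device units, so 50 units = 1%
signal change) plus slow sinusoidal drift, a feedback-locked response per
trial, band-limited measurement noise (white noise low-passed at 4 Hz —
pupil traces are smooth at the sample level), and annotated blink dropouts
(samples zeroed and invalidated) and saccade dips. The response kernel is
the canonical pupil impulse response `h(t) ∝ t^w e^{−w t / t_max}`
normalized to unit peak, with `w = 10.1`, `t_max = 0.93 s`. Per-trial
amplitude is `β0 + β_I·I + β_H·H + β_DKL·D_KL + β_acc·error + subject
offset + noise`. Feedback onsets are spaced ≥ 3.5 s (jittered 4–5 s) so
responses return to baseline. Everything regenerates bit-identically from
(config, seed).

What the generator does *not* emulate: gaze-dependent foreshortening,
visual-vs-auditory transient shape differences, non-stationary noise,
slow fatigue or arousal drifts correlated with task variables. Passing
tests therefore demonstrate the pipeline's correctness and sensitivity
under clean generative assumptions, not robustness to every artifact of
real recordings.

## Preprocessing

Steps, in order: (i) linear interpolation across missing samples and
(ii) across blink/saccade intervals, each padded by 0.15 s on both sides
(overlapping padded spans merged; edge gaps filled with the nearest kept
value); remaining artifacts are detected from the first derivative against
a threshold (default 10 units/sample — device-dependent, configurable) and
interpolated the same way; (iii) zero-phase third-order Butterworth
band-pass 0.01–6 Hz (forward–backward filtering preserves feedback-locked
latencies); (iv) nuisance responses estimated by FIR deconvolution — one
boxcar basis set per artifact kind over [0, 6] s at 20 Hz design
resolution, ordinary least squares, events timed at artifact interval ends
(eye reopening) — and subtracted; (v) percent signal change relative to the
temporal mean of the interpolated (pre-filter, pre-residualization)
signal: the filtered and residualized signals are ~zero-mean, so the only
meaningful reference is taken before the band-pass.

Epochs are cut at the nearest sample around each feedback onset over
[−0.5, 3.0] s; trials whose window leaves the recording are dropped with a
warning. Baselines are per-trial means over [−0.5, 0) s and subtracted.
Window means use half-open intervals at sample resolution: early
[0.75, 1.25) s (centered on the canonical response peak), late [2.5, 3.0) s.
RT outliers are excluded at |z| > 3 within participant.

A known interaction deserves emphasis: the 0.01 Hz high-pass removes
session-scale signal, and the learner variables *are* session-scale (they
decay over trials). Planted-effect recovery therefore calibrates the
chain's deterministic gain with a noise-free replicate of the identical
design before comparing recovered to planted coefficients; without this
calibration a recovery criterion would conflate filter distortion with
estimation error.

## Statistics

* **Correlation time courses**: per participant, Pearson r across trials
  between each post-feedback timepoint and a model variable, Fisher
  transformed (`z = atanh r`, clamped at 1 − 1e-12). Group inference is on
  z; `tanh(mean z)` is reported for display. Participants with a
  zero-variance regressor in a subset are missing-coded and excluded.
  For the time-course stage, epochs are decimated to 20 Hz — the trace is
  already low-passed at 6 Hz, and cluster inference does not benefit from
  denser sampling.
* **Cluster-based permutation test**: one-sample t per timepoint;
  cluster-forming threshold is the two-sided t critical value at α = 0.05;
  cluster mass is the summed |t| of each contiguous suprathreshold run;
  the null is the maximum cluster mass over per-participant sign flips
  (default 10,000, seeded); cluster p is the fraction of the null at or
  above the observed mass, counting the observed statistic once.
* **FDR**: Benjamini–Hochberg step-up, used where the cluster test does not
  apply.
* **Within-subject ANOVA**: balanced designs on per-participant condition
  means, any number of within factors; participants with missing cells are
  excluded and reported. Effects are computed via orthonormal (Helmert)
  contrasts; each effect's error term is its interaction with subject;
  Greenhouse–Geisser ε comes from the covariance of the effect scores and
  corrects the p-value whenever the effect has more than one numerator df;
  generalized eta squared uses all error strata (subject plus every
  effect × subject term) in its denominator. Verified against an
  independent reference implementation.
* **Wilcoxon signed-rank**: exact enumeration for n ≤ 25, normal
  approximation above; matched rank-biserial `r_rb = (W⁺ − W⁻)/(W⁺ + W⁻)`.
* **Hierarchical models**: random-intercept linear models fitted by maximum
  likelihood (statsmodels MixedLM). The predictive criterion is a grouped
  K-fold (default 5, folds stratified within subject) cross-validated
  expected log predictive density with Gaussian plug-in predictive
  densities; the comparison ratio is |ΔELPD| / SE(ΔELPD) over pointwise
  differences, with ratio > 2 flagged meaningful. This is a deterministic,
  desk-scale criterion with the same decision contract as MCMC-based
  PSIS-LOO; an MCMC backend can be slotted behind the same result type.
  Predictors enter on their raw scales by default; z-scoring is an option.

## Problem sizes in the validation suite

The suite exercises the study-scale designs directly where cheap (24 × 200
cue-target learner runs, 47-subject letter-color model-comparison
replicates) and uses 20 seed replicates for stochastic claims, 500
simulations for the family-wise-error calibration, and 1000 permutations
per cluster test inside simulations (10,000 remains the analysis default).
End-to-end planted-effect recovery uses 24 simulated participants at
500 Hz with the full preprocessing chain.

## Known limitations

* The ELPD criterion uses plug-in Gaussian predictive densities, ignoring
  fixed-effect estimation uncertainty; with thousands of trials per fit
  this is a second-order effect.
* The deconvolution basis (boxcar FIR, [0, 6] s, 20 Hz) is a pragmatic
  default; the optimal basis and duration for real data are unsettled.
* The derivative-spike threshold is in raw device units and must be
  re-tuned per device.
* Pooled (across participants and trials) correlations are reported for
  variable-intercorrelation checks; per-participant pooling weights can
  shift these values by a few hundredths.
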