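# Methods

`erpaware` simulates and analyzes EEG experiments in which adaptive
staircases hold a low-contrast stimulus at two awareness thresholds —
detection (experiencing *something* vs *nothing*, PAS2 vs PAS1) and
identification (experiencing the stimulus's orientation vs only something,
PAS3 vs PAS2) — while single-trial ERP amplitudes are recorded. The
scientific question the analysis chain answers is whether the visual
awareness negativity (VAN, occipital, 180–280 ms) and the late positivity
(LP, centro-parietal, 350–550 ms) are larger at the detection threshold
than at the identification threshold.

## Observer model

The paradigm's generative response model is not uniquely determined by
behavioral data, so the package adopts the simplest model consistent with
probit psychometric fits per staircase: an ordered two-probit observer.
With opacity `x` on a 0–100 scale,

    P(PAS >= 2 | x) = fa + (1 - fa) * Phi((x - mu_d) / sigma_d)
    P(PAS = 3  | x) = min(P(PAS >= 2 | x), Phi((x - mu_i) / sigma_i))

with false-alarm floor `fa` (default 0.04, matching roughly 0.9 false
alarms in ~23 catch trials) and a lapse probability (default 0.02) of a
uniformly random rating. The `min` enforces ordered-response coherence,
`P(PAS=3) <= P(PAS>=2)`, at every opacity. Defaults `mu_d = 1.05`,
`mu_i = 2.85` (opacity units) reproduce the condition-wise opacity means of
the emulated study (≈0.95/1.16 for detection, 2.80/2.90 for
identification); the probit scales (0.30 and 0.60) are not reported
anywhere for individual observers and were calibrated once so that
staircase-visited opacities spread over a plausibly narrow range around
those means. Orientation reports are drawn from a (condition, rating) →
P(correct) table; the four analyzed cells use the study's estimates
(0.51, 0.53, 0.72, 0.97) and the two rarely-visited cells
(identification/PAS1, detection/PAS3) are set to chance (0.50) and ceiling
(0.97) respectively.

## Staircases

Two interleaved staircases adjust opacity: unaware responses move opacity
up, aware responses down, either on every trial (1-up-1-down) or after two
consecutive identical responses (2-up-2-down, the generator's default —
the rule the emulated design settled on). Both rules target the 50% point
of the psychometric function. The step size halves after every second
reversal (`step_shrink_factor = 0.5`, a design choice; only "decreases" is
specified by the source procedure) and is floored at one grid unit.
Opacity lives on a discrete grid of `resolution` steps between software
opacity 0 and 1 (default 500, i.e. 0.2 units on the 0–100 scale). When a
requested move would round back onto the current level — possible once the
step has shrunk below half a grid unit — the staircase advances one grid
unit in the movement direction instead; without this rule the procedure
can lock between two adjacent levels. A `LuminanceMap` can recode grid
levels that the display cannot physically distinguish to their class-mean
opacity (idempotent by construction).

Sessions draw each trial as catch (probability 0.05, opacity 0) or
otherwise assign it to one of the two staircases with equal probability.

## Synthetic epochs

Epochs span −100..800 ms at 512 Hz across 14 channels (the six VAN and six
LP electrodes plus Fz, Cz). Each component is a raised cosine in time
supported exactly on its analysis window, uniform over its electrode set
and zero elsewhere, normalized so the window mean of a noise-free epoch
equals the programmed amplitude exactly. The single-trial amplitude of
component `c` on a trial of staircase `s` is

    amp_c = intercept_c(subject) + slope_c * (x - mu_s(subject))
            + aware * (effect_c(s) + dev_c,s(subject))

with defaults `effect_van = −2.12 / −0.46` µV (detection/identification),
`effect_lp = +1.83 / +0.43` µV, `slope_van = −3.61`, `slope_lp = +3.19` µV
per opacity unit — the estimates of the emulated study. Subject deviations
`dev` are N(0, 0.8 µV) per effect and window intercepts N(0, 1 µV);
neither SD is printed in the source, and both were chosen once as
plausible between-subject spreads relative to the effect sizes. Note the
generator has a *single* opacity slope per component, so the generating
truth of the threshold × opacity interaction is zero.

Noise is white Gaussian, 40 µV per sample (an optional 1/f mode reshapes
the spectrum at fixed per-sample SD). White noise at 512 Hz averages to
roughly 2.3 µV SD over the VAN window mean and 1.6 µV over LP — the scale
at which the study's effects are detectable but not trivial at n ≈ 24 × 300.
With probability 0.03 an epoch receives a 200–400 µV sub-2-Hz drift
and is recorded as a ground-truth artifact, so the flagger's sensitivity
is measurable. What the generator does **not** emulate: realistic scalp
topography, temporally correlated background EEG rhythms, eye blinks, or
channel-specific noise; passing tests therefore demonstrate correctness of
the analysis arithmetic and estimator calibration under the assumed
trial-level model, not robustness to real-EEG artifact structure.

`generate_dataset` (defaults: 38 subjects, 420 trials, the analyzed sample
size and session length of the emulated study) runs every epoch through
the actual measurement path — baseline correction over [−100, 0) ms,
zero-phase FIR decimation 512→256 Hz, inclusive-endpoint window means,
median + 8·MAD range-threshold artifact flagging on 30-Hz-low-passed
epochs — so the trial table's `van_amp` / `lp_amp` / `eeg_bad` columns are
measurements, not shortcuts. All randomness derives from one
`SeedSequence`; identical seeds give bit-identical tables.

## Trial selection

Per subject and staircase, consecutive non-catch trials form blocks of 16
(or 20). A block is valid when its aware count lies in the widest
symmetric range around n/2 whose Binomial(n, ½) probability is strictly
below the chance criterion: (16, .80) → 6–10, (16, .55) → 7–9,
(20, .75) → 8–12, (20, .50) → 9–11. Trailing partial blocks are invalid
(the chance rule is defined for complete blocks). Opacity is mean-centered
within each block to remove staircase drift. Subjects keep a threshold
condition only with ≥ 25 trials in both awareness cells. Amplitude
outliers beyond 3 SD of the grand mean (computed once, after the previous
filters — no re-iteration) are flagged separately per measure: a VAN
outlier leaves the LP analysis untouched.

## Inference

The trial-level models are, in formula notation,

    amp ~ 1 + awareness + opacity + (1 + awareness + opacity | subject)
    amp ~ 1 + threshold*awareness + threshold*opacity
          + (1 + threshold*awareness + threshold*opacity | subject)

with awareness coded 0/1 (unaware/aware), threshold 0/1
(identification/detection), predictors otherwise un-standardized. Under
this coding `awareness` is the identification-threshold effect and
`threshold:awareness` the change from identification to detection; the
detection-threshold effect is their sum, computed draw-wise.

"Robust" is realized as a Student-t observation model with unknown degrees
of freedom. The sampler is a purpose-built Gibbs sampler on the
scale-mixture representation (t = normal with Gamma(ν/2, ν/2) precision
mixing), which makes every conditional conjugate except ν
(random-walk Metropolis on log ν, Gamma(2, rate 0.1) prior truncated to
[1, 100]). Priors: Normal(0, 2) on every intercept and slope (the study's
stated vague prior); Huang–Wand hierarchical inverse-Wishart on the
random-effect covariance (ν = 2, A = 2, giving marginal half-t(2, 2) SDs);
half-Cauchy(0, 2) on the residual scale via the inverse-gamma mixture. The
fixed effects are drawn from the *collapsed* conditional with the subject
effects marginalized by Woodbury identities; this removes the
fixed-intercept/random-intercept funnel and brings split-R̂ to ≈ 1.004
with bulk ESS near the draw count. Defaults: 4 chains × (500 warmup +
1000 draws); `fast` mode (multiverse grids, smoke runs) 2 × (300 + 600).
R̂ ≥ 1.05 on any fixed effect flags the fit as non-converged — flagged,
never silently accepted.

Posterior indices per coefficient: equal-tailed 95% CI; probability of
direction (share of draws on the median's side, zeros counted with the
median); ROPE fraction of the full posterior inside ±0.1 µV;
Savage-Dickey BF10 = prior density at 0 / posterior density at 0, the
prior in closed form, the posterior by Gaussian KDE (Scott bandwidth) —
except when the null lies > 2.5 posterior SDs from the posterior mean,
where KDE tail noise dominates and a moment-matched normal approximation
is used instead (the same weakness motivates logspline estimators in the
R ecosystem). A posterior density below 1e-10 reports the BF as a lower
bound. Verbal labels use the conventional 3/10/100 cutoffs, as annotations
only. For derived contrasts (e.g. the detection effect) the Normal(0, 2)
reference prior is not the contrast's implied prior; its BF is reported
against that reference and should be read accordingly.

The behavioral model is a Bayesian logistic mixed model of orientation
accuracy (`correct ~ awareness * threshold` + subject intercepts,
Normal(0, 2) fixed-effect priors, half-normal(1) on the intercept SD),
sampled with emcee (64 walkers; affine-invariant ensemble) — a
deliberately different numerics engine for a low-dimensional posterior.
Complete separation is detected and reported, not fitted.

## Multiverse

The full factorial of block length {16, 20} × chance criterion {liberal,
conservative} × EEG-bad trials {excluded, included} × orientation
predictor {no, yes} gives 16 cells; each runs selection and both
full-interaction models with per-cell seeds spawned deterministically from
the base seed, so results are independent of execution order and a failed
cell (empty analysis set) never aborts the grid. The cell
(16, liberal, exclude, no-orientation) is the main analysis and reproduces
a standalone run of the same code path exactly. `summarize_robustness`
reports sign-consistency counts and CI-excluding-zero counts per effect.

## Problem sizes and numerical choices

Recovery and multiverse checks run on 24 subjects × 300 trials — enough
for every subject to clear the 25-trial cell minimum with ~100 analyzed
trials per staircase — with the fast sampler preset; full-precision
defaults are a flag away. Window endpoints are inclusive at the sample
grid (the endpoint convention is not specified by the source). Degenerate
inputs — a single subject, all-identical responses, an empty analysis
set, a chance criterion below the central binomial mass — raise or flag
explicitly rather than crash.

## Known limitations

- The generator's trial-level linear model matches the analysis model's
  likelihood family up to the Student-t/Gaussian distinction; it cannot
  probe misspecification of the window-mean measure itself.
- Savage-Dickey BFs beyond ~10^6 are extrapolations of a density estimate
  at a point the posterior never visits; they are reported as lower
  bounds.
- The per-block centering transfers any block-mean opacity signal into
  the awareness coefficient (a ~0.1 µV inflation at default settings, as
  in the real design); the recovery tests account for this by checking CI
  coverage rather than point equality.
- Real-data ingestion (tidy trial CSV + epoch HDF5) follows the writers'
  schema; vendor EEG formats are out of scope.
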