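# Methods

`fixdeconv` analyzes co-registered eye movements and EEG from free-viewing
experiments.  Its object of study is the fixation-related potential (FRP):
the EEG response time-locked to each fixation onset.  Two problems make
FRPs hard to estimate in unrestricted viewing.  First, responses last
longer (~700 ms) than fixations (~250 ms), so successive responses overlap
in the recording.  Second, low-level oculomotor covariates — saccade size,
fixation rank within a trial, vertical gaze position, fixation duration —
modulate the response and differ systematically between the fixation
categories one wants to compare.  The package addresses both with
regression-based deconvolution: one sparse linear model over the whole
continuous recording, per channel.

## Fixation categorization

A *refixation* is a fixation within `radius` (default 2 degrees of visual
angle) of an earlier fixation of the same trial; its first visit is the
*precursor* fixation; fixations whose location is never re-entered are
*ordinary*; everything else (the reference level of the model) is *other*.
The rules that resolve ambiguous geometry, in application order:

1. A fixation qualifies as a return of the **earliest** previous fixation
   `i` it lies within `radius` of, provided (a) some intervening fixation
   lay outside `i`'s radius (the region was left) and (b) it sits at least
   `radius` from the immediately preceding fixation (it arrives by a real
   displacement).  A return within radius of several mutually close early
   fixations is scored once, against the earliest.
2. In a chain of consecutive qualifying returns only the first keeps the
   refixation label; later chain members become "other".
3. A fixation that would be both a precursor and a refixation gets neither
   label (it becomes "other"); a refixation whose linked first visit loses
   its label this way keeps its own.
4. With `drop_pre_refixation` (default on), the fixation immediately before
   each refixation is reassigned to "other" — it carries return-specific
   preparatory activity.  It is reassigned rather than deleted because the
   deconvolution model must see *every* fixation; existing precursor or
   refixation labels are never overwritten by this rule.
5. Ordinary fixations are those with no other fixation of the trial within
   `radius`, before or after.

Same-location chains (consecutive fixations inside one 2-degree region,
which could equally be read as refixations of the previous or precursors
of the next fixation) fall out of these rules as "other" without a special
case.  Boundary ties are resolved strictly (`distance < radius`); they are
measure-zero for continuous positions.  `merge_ordinary_other` relabels
ordinary fixations into the reference category, reproducing the
merged-category model variant.

## Design matrix

Per-event-type Wilkinson-style formulas are supported; the standard model
is

    fixation: y ~ 1 + category + s(rank, 5) + s(duration, 5)
                  + s(incoming saccade size, 5) + s(outgoing saccade size, 5)
                  + s(y position, 5)
    stimulus: y ~ 1

Categories are treatment-coded against the "other" reference, so dummy
betas are difference waves.  Continuous covariates are expanded in clamped
cubic B-spline bases: a basis of `n` functions places `n − 2` knots on
equally spaced quantiles of the participant's own covariate sample
(endpoints included; for `n = 5` the 0th/50th/100th percentiles), with
boundary knots at multiplicity four.  The basis functions sum to one over
the fitting range, so one column per covariate (the first) is dropped for
identifiability next to the intercept; marginal reconstruction makes the
choice of dropped column irrelevant.  Out-of-range evaluation points are
clamped to the boundary.  The accounting for the standard model: 1
intercept + 3 dummies + 5 × 4 spline columns + 1 stimulus intercept = 25
predictors.

Time expansion replicates each mass-design entry at every lag of a
half-open sample window `[round(t_min·fs), round(t_max·fs))` around its
event (−200…+500 ms at 250 Hz gives exactly 175 lags, hence 4375 sparse
columns), with event times mapped to the nearest sample.  Rows outside the
recording are truncated; overlapping events sum.  Excluded stretches
(inter-trial intervals, bad eye-tracking periods) are handled by zeroing
entire rows of the expanded matrix, which removes their influence on the
fit while preserving the timing of the recording.

## Estimation and marginal FRPs

Each channel is regressed on the expanded design with LSMR (iterative
minimal-residual sparse least squares), tolerance 1e-10, initialized at
zero, at most `10 · n_columns` iterations; LSMR from zero converges to the
minimum-norm solution under rank deficiency (e.g., an empty category),
which is flagged in the diagnostics.  Channels are independent, so joint
and per-channel fits coincide.

Raw betas are difference waves plus spline partial effects without a
natural zero.  Marginal FRPs evaluate every spline at a fixed level — the
participant's mean over all fixation events entering the model — and add
that identical contribution to the intercept and each category's dummies,
so all categories are presented at the same predictor levels.  Analysis
windows are half-open `[t0, t1)` at the recording rate throughout: the
adopted baseline 0–20 ms after fixation onset covers exactly 5 samples at
250 Hz; the lambda window is 30–130 ms (100 ms centered on the 80-ms
peak); the late window 200–400 ms.  A vetting helper computes uncorrected
window measures in the two candidate baselines (−200…−100 ms and 0–20 ms)
so the group ANOVA can confirm the adopted baseline carries no category
effect.  ROIs average one landmark channel plus six neighbours (8 ROIs ×
7 channels = 56 electrodes) with region and hemisphere factor labels; for
synthetic montages the membership comes from configuration, not from any
real electrode layout.

## Group statistics

Window measures form a complete within-subject design.  Each effect is
tested with the classical univariate repeated-measures F computed from
orthonormal contrasts of the per-subject cell means; the Greenhouse–
Geisser epsilon is estimated from the contrast-score covariance and
sharpened to the Huynh–Feldt epsilon, `ε_HF = (n·q·ε_GG − 2) / (q·(n − 1 −
q·ε_GG))` with `q` the effect's numerator df, capped at 1 and floored at
`1/q`.  Both degrees of freedom are multiplied by ε before the corrected p
value; effects with one numerator df are sphericity-trivial (ε ≡ 1).
Incomplete or unbalanced designs are rejected rather than imputed.

Newman–Keuls post hocs rank the cell means and compare subrange extremes
against span-dependent studentized-range critical values, with the
stepwise gate: a non-significant range silences every comparison nested in
it.  The error term and per-mean observation count come from the ANOVA
effect the means belong to (for marginal means, the factor's main-effect
error term with `n_subjects × other-levels` observations per mean) — the
convention is a package choice, tested against its own oracle, since
stepwise procedures do not define it uniquely for interaction cells.
Saccade angles get descriptive summaries only; circular inference is out
of scope.

## Synthetic data

The generator emulates the *statistical structure* of a free-viewing
contour-search session, not its stimuli: 8-s trials on a 30×30-degree
display, gamma fixation durations (mean 247 ms, shape 5; saccade flight
time is absorbed into the duration, so onsets tile the trial), 80 analyzed
trials per participant (~2,500 fixations, the per-participant event count
the analysis is sized for).  New fixations self-avoid (minimum spacing
2.5 degrees, emulating inhibition of return) so ordinary fixations
dominate (~75%).  Revisits are planned: a fixation is designated a future
revisit target with probability 0.17 when enough trial time remains, and
revisited after ~9 intervening fixations (Normal(10, 1.5) gap, minimum 6),
landing within 0.75 degrees of the target.  The gaze approaches the target
one fixation before returning, so refixations receive the smallest
incoming saccades while designated precursors receive the largest (mean
7 vs. 4 degrees) and emit the smallest (drawn at mean 2 degrees before
spacing) — the category/covariate confounding the deconvolution must
untangle.  The asymmetry is a flag (`asymmetric_saccades`) so pipelines
can be tested with and without confounding; saccade *angles* are uniform
(no angle effects are modeled).

EEG is linear superposition plus noise.  Components: a lambda-like
occipital wave (Gaussian, peak +8 µV at 100 ms, σ 20 ms) scaled by a
saturating function of incoming saccade size; a late parieto-occipital
negativity (−3 µV at 300 ms, σ 60 ms) scaled linearly by fixation rank; in
the `default` preset, a precursor-only raised-cosine offset (−2 µV peak,
−1 µV window mean) supported exactly on 200–400 ms; and a stimulus-onset
response (+5 µV at 120 ms).  Effect functions are normalized to 1 at the
generator's expected covariate mean.  Topographies assign region-level
weights (occipital strongest, frontal near zero or sign-inverted) over a
synthetic montage of 8 region×hemisphere sites (1 or 7 channels per site).
The `null` preset is identical with the category offset removed.

Noise is white Gaussian, σ = 2 µV per sample.  This is a deliberate
convention, not an EEG background model: band-limited resting EEG is
larger and autocorrelated, but the emulated analysis buys its precision
through ~1.3-million-sample recordings and 21-participant grand averages,
which a desk-scale simulation cannot afford.  The noise floor is sized by
a precision argument — with ~200 precursor events, a dummy-coefficient
standard error of σ/√n ≈ 0.15 µV — so that one simulated session reaches
the per-beta precision of the full-scale analysis.  A pilot noiseless run
puts the estimator's own bias floor at NRMSE ≈ 0.004, so recovery error
scales linearly with σ.  What passing recovery tests therefore show is
that the *estimator* is correct and well-conditioned under realistic
overlap and confounding — not that effects of this size are recoverable
from a single real recording at raw-EEG noise levels.

Other simplifications: no ocular artifacts (cleaning is upstream and out
of scope), no 1/f spectrum by default, no head model (topographies are
abstract weights), no immediate (lag-2) revisits, and kernels are
truncated at 500 ms so the estimation window contains them — the forward
model refuses kernels longer than the window, which would make recovery
ill-posed by construction.

## Evaluation studies and problem sizes

`fixdeconv.evaluation` packages three studies, with sizes chosen as the
package's standard desk-scale configuration:

- **Kernel recovery** — one default-preset session (~2,500 fixations, 8
  channels, 200,000 samples, 4,375 columns), scored as NRMSE
  (`rms(error)/rms(truth)` over channels × 0–500 ms lags, both
  baseline-corrected at 0–20 ms) per category, against the same score for
  the naive event-locked average, plus the recovered precursor−ordinary
  occipital late-window offset against its configured value (−1 µV window
  mean).
- **Type-I calibration** — 2,000 replicates of a compound-symmetric null
  (21 participants × 3 levels: participant intercept SD 1 plus unit cell
  noise), testing the HF-corrected category effect at α = 0.05.
- **Power** — 200 replicates of 21-participant studies whose window
  measures are drawn around the preset's true cell means (between-subject
  SD 1.0 µV, within-cell SD 1.2 µV, compound-symmetric — realistic
  pipeline-output variability).  Full-EEG deconvolution for 21 × 200
  sessions would be prohibitive; the measurement-level draw emulates the
  pipeline's output distribution instead, while the full EEG path is
  exercised once in the recovery study.

## Known limitations

- The labeling attribution rule (earliest qualifying first visit) and the
  chain/double-role conventions are one consistent reading of informally
  stated selection criteria; alternatives (e.g., attributing to the
  nearest rather than earliest first visit) would relabel a small fraction
  of fixations.
- Covariate imputation at the participant median (trial-initial incoming
  and trial-final outgoing saccades) slightly shrinks spline-edge
  estimates.
- No regularization, temporal basis functions, spline interactions, or
  cross-validated model selection; severe collinearity is reported only
  through solver diagnostics.
- The Huynh–Feldt formula is applied per effect with `q` = effect df; for
  interactions this generalization (shared with common statistical
  packages) is a convention rather than a derivation.
- The simulator's revisit process is Markovian bookkeeping, not a model of
  memory or saliency; rank densities for precursors/refixations skew
  early/late as in real data, but trial-level dynamics (ambient-to-focal
  transitions) are not otherwise reproduced.
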