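# Methods

## The estimation problem

The compensatory reserve measurement (CRM) maps a subject's position
between normovolemic baseline (CRM = 1) and hemodynamic decompensation
(CRM = 0). In a lower-body negative pressure (LBNP) session the label
is `1 − LBNP / LBNP_HDD`, a stepwise-constant staircase that drops as
chamber pressure steps down and reaches 0 at the subject-specific
decompensation step. The pipeline learns this label from per-beat
morphology of the arterial pressure waveform, so that the features
driving the estimate remain physiologically interpretable.

## Synthetic cohort generator

The human LBNP datasets this method targets are held in a restricted
repository, so the package ships a simulator that reproduces the
*statistical structure* the estimator must exploit, not any particular
device's signal.

**Protocol.** Nine steps, pressures (0, −15, −30, −45, −60, −70, −80,
−90, −100) mmHg, 300 s each by default. Only the endpoints and step
count of the canonical protocol are fixed by convention; this ladder is
one reasonable staircase and is fully configurable. Cohorts draw
decompensation steps from {4..8} with equal counts per group; the
sparse extremes (steps 2, 3, 9) are not simulated. Sessions truncate at
the decompensation step, and labels are constant within a step (no
interpolation across transitions).

**Beat model.** One cardiac cycle is a diastolic baseline plus two
positive Gaussian components: a systolic wave at `mu1` with width `s1`,
and a delayed reflected wave (relative amplitude 0.4) producing the
post-systolic inflection. All timing parameters are proportional to a
single timescale `h`, the subject's half-rise→inflection delay
(`s1 = 0.30 h`, `mu1 = 0.96 h`, reflected delay `1.30 h`, reflected
width `0.45 h`), which makes the landmark geometry contract rigidly and
monotonically with `h` and guarantees exactly one early post-peak
curvature sign change in the noise-free limit. The pulse is rescaled on
the sample grid so peak-minus-foot equals the target pulse pressure
exactly.

**Effect sizes.** At CRM = 0, relative to baseline: pulse pressure
falls to 50%, heart rate rises by 40%, and `h` falls to 55%, all
linearly in (1 − CRM). These magnitudes are in the range reported for
progressive central hypovolemia up to decompensation and are strong
enough that feature-based models can recover CRM on held-out subjects;
they are constants of the generator, configurable but not tuned per
experiment.

**Subject variability and noise.** Baselines are drawn per subject:
systolic pressure N(125, 10) clipped to [100, 160] mmHg, pulse pressure
N(48, 7) → [32, 65] mmHg, heart rate N(64, 8) → [45, 100] bpm, `h`
N(0.25, 0.03) → [0.17, 0.33] s — healthy-adult ranges. Measurement
noise is white Gaussian, sd 1 mmHg; baseline wander is a 0.2 Hz
sinusoid of amplitude 2 mmHg with random phase. Both exist chiefly to
make the lowpass stage and the beat detector do real work. Every
subject's seed derives from the cohort seed, so cohorts are bitwise
reproducible.

**What the generator does not emulate** — respiration coupling,
arrhythmias, baroreflex dynamics, device transfer functions, motion
artifacts, or any nonlinear label/waveform relation beyond the
monotone one built in. Passing tests therefore demonstrate that the
pipeline's machinery is correct and can recover a CRM-like signal from
realistic-looking beats; they do not certify accuracy on human data.

## Preprocessing

* **Filter**: Hamming windowed-sinc FIR, 101 taps, 20 Hz cutoff at
  500 Hz sampling, applied centred (edge-padded convolution) so the
  linear phase cancels. The filter family is conventional for pulse
  waveforms; the cutoff preserves pulse morphology (systolic rise
  content sits below ~15 Hz) while removing the injected noise band.
  DC gain is unity by construction. A windowed sinc has finite
  passband ripple (≈2 × 10⁻³ gain deviation at 2 Hz for this design),
  so re-filtering an already-band-limited signal reproduces it to the
  few-per-mille level, not to machine precision; the idempotence
  property test uses a 10⁻² tolerance accordingly.
* **Beat detection**: systolic upstrokes are first-derivative peaks
  (height ≥ 33% of the maximum upslope, refractory 0.3 s); each foot is
  the pressure minimum in the 0.25 s window before its upstroke. Beats
  are foot-to-foot; an incomplete trailing beat is dropped.
* **Landmarks**: A = beat-start foot; C = beat maximum; B = first
  rising-limb sample at or above the A–C amplitude midpoint (amplitude,
  not temporal, midpoint — consistent with the half-rise literature);
  D = first sample after C where the second derivative crosses from
  negative to positive. The second derivative is computed by central
  differences after a symmetric 5-sample moving average, which
  suppresses discretisation ripple without phase shift; the crossing
  test is tolerance-free on the smoothed signal. No crossing before
  the next foot ⇒ the beat is excluded (`no_inflection`); several
  crossings ⇒ the first is kept. Beats shorter than 5 samples, with a
  peak at the boundary, or with no proper half-rise are `malformed`.
  On noise-free model beats, detected B/C/D fall within one sample
  (2 ms) of the analytic roots of the closed-form derivatives.

## Feature catalogue

Six phases are delimited by the landmarks: sys_rise (A→C), sys_dec
(C→D), sys (A→D), dec (C→A′), dia (D→A′) and the whole beat (A→A′).
The 54 features partition as 7 individual (systolic/diastolic/
inflection pressures, PP, PPI, HR, SI), 6 durations (incl. HRIP =
t(D) − t(B)), 5 phase means, 5 trapezoidal areas, 10 normalized areas
(per-phase and per-beat sample counts), 18 NODIA features (areas,
means and phase-normalized areas over all six phases after
re-referencing pressure to P(D)), and 3 slopes. Choices worth noting:

* **SI** is defined as the inflection ratio `(P(D) − P(A)) / PP`.
* **dec** (peak → next foot) is distinct from **sys_dec** (peak →
  inflection) so the corresponding area names denote different
  quantities.
* **PPI** is the interval between consecutive systolic peaks; the
  table builder passes the true next-peak interval, and an isolated
  beat falls back to its foot-to-foot length.
* Phase endpoints are inclusive sample indices; A′ maps to the last
  sample before the next foot, so a "zero-duration phase" is an error
  rather than a silent NaN.
* Rows are per beat (no windowed averaging); an optional 10-beat
  rolling-median smoother is available for prediction-time smoothing
  and is off by default.

The registry (name, category, unit, formula string) is the single
source of truth: the extractor, table column order and JSON export all
derive from it, so a corrected formula swaps in without touching the
pipeline.

## MRMR ranking

Relevance and redundancy are plug-in mutual information (nats) on
joint histograms with equal-frequency binning of each variable
(⌈√n⌉ bins, capped at 64; the continuous CRM target is binned the same
way). Equal-frequency binning makes the ranking invariant to strictly
monotone transforms of any single feature. Greedy forward selection
maximises `relevance − mean redundancy` against the already-selected
set (difference scheme; a quotient scheme is available), with ties
broken by registry order so rankings are exactly reproducible.

## Models

Linear regression (OLS), regression trees with minimum leaf sizes
4/12/36 (the conventional fine/medium/coarse presets), bootstrap
aggregation of 30 eight-leaf trees, and least-squares gradient boosting
(30 trees, leaf 8, learning rate 0.1, depth 3). Predictions are raw by
default — estimated CRM may over/undershoot [0, 1], matching how such
regressors are used; clamping is an explicit option. Fitted models
serialise to self-describing JSON (coefficients, or nested node arrays
per tree) and reload as standalone predictors.

## Evaluation

Perfect metrics take residuals about the identity line: P-RMSE =
√mean((ŷ−y)²), P-R² = 1 − Σ(ŷ−y)²/Σ(y−ȳ)². Conventional metrics come
from the least-squares fit of predictions on calculated CRM (that
orientation is recorded in every report): R² is the squared Pearson
correlation and RMSE the residual about the fitted line. Algebraically
RMSE ≤ P-RMSE and P-R² ≤ R²; P-R² may be negative. A constant label
vector makes P-R² undefined — it is returned as NaN with a warning
(P-RMSE remains valid), while the conventional fit raises. Metrics are
pooled over beats within a test group by default; per-subject averaging
is available as an option. The subgroup matrix trains one model per
decompensation group (each with its own top-10 ranking) and
cross-evaluates every model against every test subgroup, rejecting any
subject overlap between a model's training set and a test table.

## Problem sizes and tolerances

The default protocol is 300 s per step. Validation runs (the test
suite and `scripts/acceptance.py`) use 60 s steps with the full
12-subjects-per-group, 8:4-split cohort — ~70–90 beats per step and
~19 000 training beats, which the package treats as its standard
validation problem size. Stochastic checks run over five pinned cohort
seeds with a majority-must-pass rule. Oracle-equivalence tolerances:
10⁻¹² absolute for mutual information and metric formulas against
brute-force reimplementations, exact sequence match for greedy MRMR
against exhaustive enumeration, 1% for trapezoidal areas against
10×-oversampled Riemann sums, one sample (2 ms) for landmarks against
analytic root-finding, and one ulp for one-learner bagging against the
single tree (the mean-of-one division costs a rounding).

## Known limitations

* The synthetic beat is a two-Gaussian caricature: no dicrotic notch
  proper, no incisura, and a single inflection by construction.
* The feature formulas are reconstructed from the catalogue's category
  structure and naming conventions; alternative definitions of SI or
  of the normalization denominators would slot into the registry.
* Stepwise labels mean within-step feature variation is noise by
  definition; models cannot (and should not) resolve sub-step reserve
  changes in this cohort.
* MRMR scores depend on the binning; rankings are stable across the
  tested seeds but the estimator is the simple plug-in, with no bias
  correction.
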