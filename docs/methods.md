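# Methods

This note documents the models, conventions and design choices behind
`fmriseq`, in the spirit of a package reference: what is computed, under
which assumptions, and what the synthetic data do and do not show.

## Single-event response model

The multivariate decoding probability following one visual event is
modeled as a single sine cycle flattened to baseline outside the cycle
(`fmriseq.core.eval_response`). Parameters, all in probability/TR units:

| parameter | meaning | default (simulation) |
|---|---|---|
| A | peak deviation from baseline | 0.6 |
| λ = 1/f | response duration in TRs | 5.24 |
| d | onset delay in TRs | 0.56 |
| b | baseline probability | 0.05 |

λ and d are the group-average values obtained by fitting this model to
occipito-temporal decoding time courses; A and b are free simulation
choices on the scale such curves actually span. Time is counted in TRs
(1 TR = 1.25 s), with TR *i* of a trial window acquired at t = i − 1 from
sequence onset.

`fit_response` minimizes the sum of squared residuals under box
constraints (A ∈ [0,1], λ ∈ [1,13], d ∈ [0,3], b ∈ [0,1]) with COBYLA,
followed by a Nelder–Mead polish that tightens the optimum to numerical
precision (COBYLA alone converges slowly near the minimum in this
implementation). Initialization is data-driven: A from the data range, b
from the first sample, d = 0.5 TR, λ from twice the time of the maximum.
Non-convergence is reported in the result, not raised. On noiseless
curves all four parameters are recovered to 1e−3; at Gaussian noise
σ = 0.02 the median absolute λ error is ≈ 0.1 TR over 200 replicates.

## Two-event difference wave and derived quantities

The difference between two responses shifted by δ is a single-cycle sine
with wavelength λ + δ, frequency f_δ = f/(1+fδ) and amplitude factor
A·sin(2πfδ/2) (`difference_waveform`). Two conventions deserve note:

- **Amplitude sign.** The closed-form factor is a meaningful signed
  quantity only up to δ = λ/2 (it grows monotonically there). Taken
  literally it turns negative for δ > λ, although the difference of two
  non-overlapping responses is still positive-then-negative. We therefore
  use the magnitude |A·sin(πδ/λ)| and keep the canonical forward-early
  sign; for δ ≤ λ/2 this is identical to the closed form.
- **Two δ definitions.** Period windows use the onset-of-first to
  onset-of-last offset in TRs, δ = (n−1)(ISI+dur)/TR (e.g. 0.42 TRs at
  32 ms). Frequency prediction uses the onset-to-offset span in seconds,
  δ = (n−1)·ISI + n·dur (0.628 s at 32 ms). Both are separate, explicitly
  named operations (`delta_trs`, `delta_seconds_total`).
- **Unit convention for f_δ.** The conventional predicted frequency
  plugs the span in seconds into f in per-TR units, i.e. 1/(λ + δ_s),
  and labels the result Hz: 0.17 for 32 ms, 0.07 for 2048 ms. This
  mixed-unit quotient is the default (`convention="paper"` replicates the
  printed values); a dimensionally strict mode divides the per-TR
  frequency by the TR duration (`convention="strict"`, 0.141 true Hz at
  32 ms). The spectral module consistently counts time in TR units, so
  spectra peak near the conventional values.

`compute_periods` maps the continuous forward/backward boundaries to
inclusive 1-based TR windows by half-up rounding of the start
(round(d)+1), a ceiling at the forward/backward split, and capping the
final TR at the window length. This is the only simple rule consistent
with all ten published window boundaries across the five speed
conditions, including the 13-TR cap at 2048 ms; half-up (not banker's)
rounding is used. The repetition-trial window TRs 2–7 does *not* follow
from this rule applied to the 9-item geometry and is kept as a literal
constant in `repmetrics`.

## Sequentiality metrics

Probabilities are first normalized by their trial-wise sum per class
(columns sum to 1 over the trial; `normalize_trialwise`), exactly as
phrased in the source analyses; a per-TR simplex normalization is
available separately. Per TR:

- **slope** — sign-flipped OLS slope of probability on serial position
  (positions centered); positive = forward. The flip is applied at the
  metric level, which is algebraically identical to flipping averages.
- **rank correlation** — Kendall's τ (scipy), sign-flipped likewise.
- **mean step** — classes sorted by descending probability (ties broken
  by lowest class index), mean of successive differences of their serial
  positions; +1 for a perfectly forward-ordered TR. The
  sort-and-successive-difference reading of "mean step size between
  probability-ordered events" is adopted; the phrase is not fully
  specified in the source.
- **decoded position** — serial position of the argmax class, ties to
  the lowest class index (deterministic; ties are measure-zero on real
  data but common on toy inputs).

Early/late transition means use literal speed-specific TR-pair sets
(e.g. 2→3 early-forward at 32–128 ms; triplets at 2048 ms). Item-removal
controls either mask each TR's argmax or drop the first/last item's class
entirely, renormalizing and shortening the speed condition so windows are
recomputed with the reduced span.

## Decoding stage

Five independent binary L2-logistic regressions (C = 1, lbfgs, ≤ 4000
iterations, tol 1e−4), one per class against a pooled "other" class, with
class weights inverse to training frequencies. "Multinomial … one-vs-rest"
is contradictory terminology; the operative one-vs-rest description is
implemented. Runs are linearly detrended per feature and z-scored per run
(the run being the test set when applied in leave-one-run-out
cross-validation; training-statistics z-scoring is the `preprocess`
caller's choice). Training samples are the volumes nearest onset + 4 s
(the fourth TR at 1.25 s). A top-k F-statistic feature selector
(`select_features`) stands in for voxel selection; it is a simplified
substitute, not an attempt to reproduce mask-based selection. Raw
one-vs-rest probabilities are *not* forced to sum to 1; normalization is
downstream.

## Synthetic data: what it emulates, what it does not

`synth` generates the full task structure with exact counterbalancing
(see README). Two generator choices matter for interpretation:

- **Classifier saturation (`sharpening`, default 60).** The probability
  tier forward-simulates each event's response into its class and
  normalizes rows; for heavily overlapping fast sequences this yields
  near-uniform rows, far less dispersed than real decoder output, because
  logistic classifiers turn small evidence differences into saturated
  probabilities. Raising the normalized rows to a power restores a
  realistic dispersion (per-TR probability SD ≈ 0.18 in the 32 ms
  condition, versus ≈ 0.20 reported empirically) while preserving all
  within-TR orderings and hence every sign-based sequentiality property.
  The exponent was calibrated once against that reported dispersion.
- **Rest stand-in.** Real rest decoding output has no generative
  description; `simulate_rest` uses an AR(1) Gaussian process on class
  logits mapped through softmax — a logistic-normal approximation to
  low-concentration Dirichlet draws (concentration 0.5, AR coefficient
  0.3, defaults). It reproduces the wildly fluctuating, single-class-
  dominated rows of real rest (per-TR SD ≈ 0.24) but its slope time
  course is spectrally much whiter than real, BOLD-autocorrelated rest.

Consequences for what passing tests show: zero-noise sequence trials
reproduce the qualitative core results deterministically (positive
forward / negative backward period slopes at every speed; slope time
courses correlating with the predicted difference wave at r ≥ 0.91;
concatenated-trial spectra peaking within 0.02 of the predicted
frequencies). The sparse-event insertion analysis, however, is
*harder* in this synthetic world than on real data: the fast (32 ms)
difference wave occupies only ~6 of the 12 inserted TRs, and the white
rest background is comparatively loud in the 0.17 band. The measured
paired effect of six κ = 0.8 fast inserts on fast-band power is
d ≈ 0.24–0.31 across independent 50-replicate streams — about half the
effect reported on real data at the same settings — so the corresponding
50-replicate significance test has only ~40% power and is expected to
fail for some seeds. Raising the rest AR coefficient rescues the fast
band but symmetrically degrades the slow band (a red-shifted background
is quieter at 0.17 and louder at 0.07), so the defaults were kept rather
than tuned. Slow-insert detection (d ≈ 0.7) and the probability-SD
signature of fast inserts (|d| > 8) are robust. A further limitation:
sharpened *slow* (2048 ms) trials are over-dispersed (SD ≈ 0.40 versus
≈ 0.22 empirically), so the small SD decrease reported for slow sequences
is not reproduced — only the fast-condition SD ordering is.

The κ-blending itself follows the source procedure exactly: inserted
segments are κ·trial + (1−κ)·donor, donors drawn from non-overlapping
random rest locations so κ = 0 carries identical concatenation artifacts,
and the same segments/locations are reused across κ levels.

## Spectral analysis

Slope series (per-TR slopes on rest or on concatenated trial windows,
original timestamps preserved so concatenation leaves gaps) are analyzed
with the Lomb–Scargle periodogram (scipy implementation), which is exact
for uneven sampling; on even grids it reduces to the classical
periodogram (asserted against an FFT oracle in the tests). The frequency
grid runs from 1/(span·oversample) to the Nyquist frequency of the median
sampling interval, oversampled ×2; power is variance-normalized, scaled
to unit total ("normalized spectra"; the divide-by-total choice is
config-exposed), and smoothed with a 0.005-wide running mean whose window
shrinks at the edges. Band power is the mean over a ±0.01 closed band
around the predicted frequency, matching the smoothing. For rest data
without a known ordering, spectra are averaged over all 120 candidate
serial-position assignments, making the result invariant to class
relabeling. When rest is compared against 15 concatenated 12-TR trial
windows, rest is trimmed to its first 180 TRs to match lengths.

## Statistics

One-sample and paired t-tests (scipy) with Cohen's d = (mean − null)/SD
(one-sample) or mean(diff)/SD(diff) (paired); one-sided confidence
intervals are reported in the half-open [lower, +∞) style.
Benjamini–Hochberg and Bonferroni corrections via statsmodels. Linear
mixed-effects models and Tukey post-hoc comparisons are deliberately out
of scope; the package provides the descriptive and t-test layer only.

## Problem sizes

Default problem sizes are those of the task design itself: 600 slow
events in 8 runs, 75 sequence trials, 45 repetition trials, 233-TR rest
runs, 13-TR trial windows, 12-TR inserts, 15 trials per speed for
concatenation, and 50 rest replicates for insertion sweeps. The voxel
tier defaults to 60 voxels with unit-norm class templates at exact
pairwise correlation −0.25 (a centered-simplex geometry emulating the
negative template correlations seen empirically); decoding demonstrations
use 4 runs of this tier.
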