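# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of the `hreflex` package. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from elsewhere.

## Recruitment-curve models

The M-wave recruitment curve is a three-parameter saturating logistic of
stimulation intensity *s* (mA): asymptote `M_max` (µV), center `c_m` (mA),
slope `b_m` (1/mA). The H-reflex recruitment curve is a five-parameter
"hill" curve — the product of a rising and a falling standard logistic —
which is bell-shaped whenever the rise center lies below the fall center
(enforced as an invariant). Both are fitted by bounded nonlinear least
squares (`scipy.optimize.curve_fit`, trust-region reflective) with analytic
Jacobians.

**Multi-start policy.** Five deterministic starts derived from the data:
amplitude from the per-step mean maximum, centers from half-amplitude
crossings of the per-step means, slopes on a geometric grid spanning
0.5–8 spans⁻¹ (logistic) / 1–10 spans⁻¹ (hill). Bounds: slopes in
(0.01, 10] /mA, centers within the measured intensity range ±50 %,
amplitudes up to 3× (logistic) / 6× (hill) the observed maximum. The best
final residual wins, so the fit is a deterministic function of the data.
The hill parameterization is swap-symmetric; fitted parameters are
normalized so the rise precedes the fall.

**Extracted parameters.** `H_max` and `stim@Hmax` come from a 0.01 mA grid
search over the measured range extended by one ramp step (robust to any
re-parameterization; a brute-force 0.001 mA scan is the test oracle).
`M_threshold` has no universal numeric definition; it is operationalized as
the smallest grid intensity where the fitted M-wave reaches 5 % of the
fitted `M_max`, and the fraction is configurable and echoed in the output
metadata. Curve MSEs are computed on data and fit divided by the fitted
maximum of the respective response — dimensionless, hence comparable and
averageable across subjects; raw µV² MSEs are emitted alongside. Ties in
"smallest intensity where…" resolve to the first grid point meeting the
criterion. The target intensity is the 10 %-of-`M_max` crossing, with an
advisory flag when the fitted H-reflex there is below 75 % of `H_max`; a
crossing outside the measured range is an error rather than an
extrapolation.

## Synthetic EMG generator

The generator emulates a soleus recruitment-curve run under background-EMG
gated stimulation: an intensity ramp in fixed steps (default 1 mA, 4 trials
per step, 50 mA safety cap, ~1 Hz stimulation with 10 % inter-stimulus
jitter), stopping early once the true M-wave has exceeded 99 % of its
asymptote for two consecutive steps. Per trial, at the 3200 Hz base rate:

- a 1 ms biphasic stimulus artifact (±500 µV) at the trigger;
- an exponential electrode-interface decay tail (120 µV, τ = 1.2 ms);
- an M-wave template: Gaussian-tapered one-cycle sinusoid with main peaks
  4 ms apart (8 ms support from 7 ms latency) — a sharp biphasic compound
  action potential;
- an H-reflex template: one-cycle sinusoid whose half-period equals the
  5 ms positive-to-negative peak separation (10 ms support from 30 ms
  latency), i.e. a ~100 Hz wavelet;
- band-limited Gaussian background noise (10–500 Hz, 5 µV RMS by default).

Templates are scaled so that the MRV inside the canonical measurement
window (M: 6–23 ms, H: 28–45 ms post-trigger) equals the ground-truth
recruitment value exactly at the generation rate; trial-to-trial
variability is multiplicative log-normal with unit mean and CV 0.15
(keeps amplitudes positive). The trigger is placed with up to 12.5 ms of
uniform jitter inside the record so that integer decimation later produces
realistic trial-to-trial trigger-quantization jitter. Cohorts draw subject
truths from documented uniform ranges (e.g. `M_max` 200–400 µV, `c_m`
18–30 mA, H rise center 7–10 mA below `c_m`) via per-subject
`SeedSequence(master_seed, spawn_key=(i,))` children, so enlarging a cohort
never perturbs existing subjects.

**What the generator does not emulate**, and what passing tests therefore
do not establish about real data: multi-phasic response morphology and
latency variability, amplitude-dependent artifact size, non-stationary or
task-dependent background EMG, electrode lift-off or movement artifacts,
and any physiological coupling between M and H amplitudes beyond their
common intensity dependence. Findings about *rate robustness of the target
intensity* transfer to the extent that real responses have comparable
spectral content; the template fundamentals (M ≈ 125 Hz effective content,
H ≈ 100 Hz) were chosen as typical for soleus.

## Degradation path

Lower rates are produced by a 2nd-order Butterworth anti-alias low-pass
followed by keep-every-k-th decimation. The cutoff rule is
`0.3125 × target_rate`, giving 200 Hz at 640 Hz and 100 Hz at 320 Hz and
generalizing to the interim rates (500/250/125 Hz at 1600/800/400 Hz). The
anti-alias filter is zero-phase (forward–backward) by default because the
degradation is applied retrospectively and a causal filter's group delay
would bias fixed-window measurements; the 10 Hz high-pass of the
acquisition path defaults to causal. Both are overridable, and the phase
choice is a sensitivity-analysis point. Trigger indices map by floor
division — the worst-case, deterministic-direction model of trigger
quantization — and the lost sub-sample offset is recorded per trial.
At 320 Hz the anti-alias cutoff sits exactly on the H-reflex fundamental:
rates below 320 Hz are out of the method's intended regime and only produce
a warning.

Consequences measured on noiseless runs: the H-reflex MRV changes by ~1 %
at 640 Hz and ~26 % at 320 Hz; the sharper M-wave by ~8 % and ~39 %. The
degradation is monotone in the decimation factor and hits the M-wave
hardest — the physically expected ordering, which the property tests
assert (they do not pin exact attenuation values, which depend on template
sharpness).

## Response measurement and delineation

Each 600 ms epoch (−200 to +400 ms, half-open on the right) is blanked for
3 ms after the trigger (1 ms pulse plus margin for ringing) and corrected
by subtracting an exponential `a·exp(−t/τ)` fitted over 3–15 ms on the
average of the lowest-intensity (sub-threshold) trials — below the
recruitment thresholds that window contains only decay and noise. τ is
bounded in (0.1, 50] ms; a non-convergent fit falls back to no subtraction
with a flag. Per-trial response MRVs then have the trial's pre-stimulus
baseline MRV (−150 to −50 ms) subtracted, because the rectified noise
floor differs between sampling rates after anti-alias filtering and the
curve models carry no offset term. The corrected values are deliberately
left unclipped: clipping at zero adds a positive bias that grows as
samples-per-window shrink, i.e. a rate-dependent floor that would shift
fitted thresholds systematically across rates.

Automated delineation divides 3–60 ms post-trigger into 1 ms bins (one
sample per bin at rates where a 1 ms bin would be empty), computes each
bin's rectified-mean amplitude per intensity step, and regresses it on
intensity with a constant, a logistic, and a hill model. A bin is labelled
M when the logistic beats the constant fit by ≥20 % MSE reduction, and H
when additionally the hill fit halves the logistic residual and is
genuinely bell-shaped (interior peak, fallen below 75 % of its maximum by
the ramp top) — the margin is needed because the hill nests a monotone
rise and would otherwise always win on extra parameters. The windows are
the longest contiguous M run and the longest contiguous H run after it
(at least two bins each; overlaps shrink at the shared boundary). This
procedure is this package's own reconstruction of automated response
delineation; every knob is exposed as a parameter. Manual mode takes
fixed windows from configuration (defaults: the canonical bands), never
from the data.

## Statistics

Friedman's test uses within-subject mid-ranks; Kendall's
*w* = χ²/(N(k−1)) is computed from the tie-uncorrected χ² so it stays in
[0, 1] by construction, while the tie-corrected χ² drives the p value
(χ²_{k−1} reference). An exact mode enumerates the within-subject rank
permutations for small matrices. Post-hoc comparisons refer
|ΔR̄|/√(k(k+1)/(12N)) to the studentized range with infinite df
(Tukey–Kramer on ranks); at k = 2 this reduces to the Friedman p. The ICC
is the two-way, absolute-agreement, single-measurement form computed from
ANOVA mean squares, with the Satterthwaite-df confidence interval
(cross-checked against an independent implementation in the tests).
Equivalence uses the 90 % CI-inclusion rule on paired differences —
operationally two one-sided t tests at α = 0.05 — against ±1 mA bounds for
stimulation intensities. Missing fits are dropped listwise with the count
reported. Note a terminological wrinkle: the classical "ICC(3,1)" label
usually denotes the consistency form; this package follows the verbal
specification (absolute agreement) and says so here.

## Problem sizes and numerical choices

The default experiment is 21 subjects; the test suite exercises the
multi-rate battery at {3200, 640, 320} Hz with manual windows on that
cohort size, equivalence behaviour on 100 cohorts of 10 subjects, and
noisy parameter recovery over 50 replicates — sizes chosen so the entire
suite runs on a single CPU in well under half an hour. Bin-classification
fits inside the automated delineation run with relaxed tolerance
(ftol = xtol = 1e-4, ≤400 function evaluations): they feed a three-way
model comparison, not parameter estimates. Degenerate inputs are errors,
not guesses: empty ramps, all-zero response columns, fewer than 8 distinct
intensities, windows without samples at the given rate, threshold
crossings outside the measured range.

## Known limitations

- The stimulation-intensity invariance statistics on synthetic cohorts are
  sharper than on human data: downsampled copies of the same record are
  near-perfectly correlated, so rank tests amplify arbitrarily small
  systematic effects, and concordance magnitudes fluctuate strongly
  between cohort seeds even when direction and significance are stable.
- The automated delineation reconstruction has no external reference
  implementation to compare against; only its agreement with manual
  windows (ICC on derived parameters) is validated.
- Non-integer decimation ratios are unsupported by design; a 600 Hz
  portable condition is represented by native-rate generation instead.
- The normalized-MSE scale depends on the normalization convention; only
  within-package comparisons across rates/methods are meaningful.
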