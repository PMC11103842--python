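# Methods

## Signal model and preprocessing

A wrist accelerometer measures specific force: gravity (≈ 9.82 m/s², the
constant used throughout, matching the device's count scale of 64 counts per
g on a signed 8-bit range of −128…127) plus movement acceleration plus
sensor noise. Arm movement of interest lives above a few Hz; gravity and
slow postural re-orientation live below. The preprocessing chain therefore
high-passes each axis (5th-order Butterworth, 3 Hz cutoff, at the 32 Hz
native rate) *before* taking the Euclidean norm — the reverse order would
fold the DC gravity component into the magnitude and swamp the movement
signal. The norm is then smoothed with a 96-sample (3 s) moving average and
subsampled every 48 samples (50 % window overlap), giving a 0.67 Hz
nonnegative intensity series per arm.

Numerical choices where the procedure itself leaves freedom:

- **Filter pass direction.** Causal single pass with zero initial state
  (config `zero_phase` switches to forward-backward filtering, which has
  zero group delay but a squared magnitude response). With the causal
  default, the first 2 s of output are warm-up transient; decimated samples
  whose window starts inside that span are flagged (`n_transient`) and
  excluded from the activity-selection candidate pool, not from the series.
- **Window alignment.** Left-aligned half-open windows
  `[k·48, k·48 + 96)`; trailing samples that do not fill a window are
  dropped, so the output length is exactly `⌊(n − 96)/48⌋ + 1`. The first
  output sample carries the timestamp of its window center (start + 1.5 s).
- **Count validation.** Counts outside the 8-bit range are an error, never
  clipped: silent clipping would bias the magnitude statistic downward on
  exactly the most active segments.

## Synchronization and tail trimming

The two bands are powered on independently; the resulting offset is a
constant lag of seconds, so it is estimated on the decimated (0.67 Hz)
series, whose 1.5 s resolution matches the phenomenon, rather than on raw
32 Hz data. The estimate is the integer lag in ±90 s (config) minimizing the
**mean absolute** difference over the overlap. Two interpretive choices are
deliberate: the absolute value (a signed difference has no meaningful
minimum) and the mean rather than the raw sum (a sum over a variable-length
overlap trivially favors the shortest overlap). Ties break toward the
smallest |lag|, then toward the negative lag, making the estimate
equivariant under swapping the arms.

Trailing idle stretches — the band left running on a table — are detected as
a terminal run of decimated values below 0.01 m/s² lasting at least 300 s
(both configurable) and removed; interior and leading quiet periods are
never touched (sleep is handled downstream by the top-decile selection, not
by trimming). Trimming runs **before** lag estimation: both bands stop
moving at the same wall-clock moment, so untrimmed flat tails align at the
same recording index regardless of the true offset and drag the overlap
objective toward zero lag. After trimming and lag application the arms are
cropped to their common support, and sessions with less than a configured
minimum overlap (default 2 h) are rejected.

## Activity extraction and asymmetry

Pair activity is the sum of the two arms' magnitudes per aligned sample; the
k = ⌈0.1·n⌉ highest-activity pairs (ties to the earlier timestamp) form the
extraction set — for a 24 h recording, roughly the most active 2.5 h,
deliberately *not* required to be contiguous. Each arm's mean over the set
is its recorded acceleration; the asymmetry index
(right − left)/(right + left) of those means is zero for symmetric use and
its sign marks the weaker side. Selecting by the bilateral sum (rather than
per-arm) keeps the two arms' means on a common time base, which is what
makes the asymmetry index interpretable.

## Cohort statistics

Descriptives are medians with Q1/Q3 under the linear-interpolation quantile
rule. Deltas are T2 − T1 per patient (positive = improvement), computed only
for patients with both sessions. Spearman's rho uses mid-ranks for ties and
is the Pearson correlation of the rank vectors; the two-sided p-value is an
exact permutation enumeration for n ≤ 9 (at most 9! = 362 880 permutations,
vectorized) and the t approximation t = rho·√((n−2)/(1−rho²)) with n−2 df
otherwise. The ordinal scales produce heavy ties, which is why mid-ranking
is load-bearing rather than cosmetic. No multiple-testing correction is
applied across the nine grid cells. The pipeline's exclusion policy is
patient-level: any stage failure in any session removes the patient from
every cohort output (a completers-only analysis), with the reason recorded
in the run manifest.

## Synthetic cohort generator

The generator emulates the study conditions the pipeline assumes, with a
per-patient latent motor ability u ∈ [0, 1] as the single driver of both
arms of the measurement:

- **Recordings**: 24 h per session at 32 Hz (default), per arm: a slowly
  re-orienting unit-gravity vector (spectral content below 0.2 Hz), white
  sensor noise (σ = 0.10 m/s² per axis), and activity bouts — Poisson
  arrivals at 30/h during wake, Gaussian durations 20 ± 10 s, Hann-enveloped
  oscillations at a random frequency in 3–10 Hz with Gaussian amplitude
  2.5 ± 1.0 m/s² along a random direction. The bout band sits above the 3 Hz
  cutoff on purpose: the pipeline's filter removes everything below it, so
  synthetic "activity" placed lower would be invisible by construction.
  Both arms share one bout schedule (bimanual daily activity; config option
  for independent schedules) with the affected arm's amplitude multiplied by
  the deficit link `f(u) = 0.15 + 0.85·u` (monotone, f(1) = 1). Signals are
  quantized to 8-bit counts with saturation; parameters implying sustained
  saturation are rejected.
- **Nuisance structure**: the right device's start time is offset by a
  uniform draw in ±15 s; each arm gets a trailing constant (gravity-only)
  idle tail of uniform duration up to 15 min. Sleep is a daily 8 h block
  starting 13 h into the recording.
- **Scores**: M-MAS = round(15·clip(u + ε)), MAL subscales =
  round(150·clip(u + ε′))/30 (the 1/30 item grid), ε i.i.d. Gaussian with
  σ = 0.06, round-half-away-from-zero. T2 ability is
  clip(u + N(0.15, 0.10)), modelling rehabilitation gains.
- **Dropouts**: optionally two extra incomplete patients (one missing the
  T2 session, one with a truncated single-arm file) to exercise the
  pipeline's exclusion paths.

Every byte of output is a deterministic function of the seed. Amplitude
defaults were chosen once so that pipeline output means land in a plausible
0.5–3 m/s² range for daily activity; no claim of distributional fidelity to
any real cohort is made.

**What passing tests do and do not show.** The generator captures the
features the pipeline's correctness depends on — band-limited movement,
unilateral amplitude deficit monotone in ability, device offsets, idle
tails, ordinal score coupling — but not compensatory movement patterns,
learned non-use (ability expressed differently than amplitude), clock
drift within a session, posture-dependent sensor placement effects, or
realistic activity-intensity distributions. Recovery results on synthetic
cohorts therefore validate the *pipeline machinery*, not the clinical
interpretability of the asymmetry index on real patients.

## Problem sizes in the test and verification suites

Simulation-based tests run the generator at reduced session duration
(0.1–1 h instead of 24 h) with thresholds that scale with duration rescaled
accordingly (idle-run minimum, maximum lag, minimum overlap); generator
structure and coupling parameters are the defaults throughout. The
correlation-recovery study uses 1 h sessions, the smallest duration at which
per-patient means have enough activity bouts (~30) for the generator's
asymptotic coupling to dominate bout-sampling noise; side-of-weakness
recovery and offset recovery use 0.25 h sessions, where those properties
already hold. The null-calibration study checks the t-approximation's
type-I error at n = 18 over 2000 replicates.

## Known limitations

- A single constant lag per session: no continuous clock-drift correction
  or sub-sample interpolation.
- The top-decile fraction applies to retained (post-trim) samples, so the
  selected duration varies slightly with trimming.
- Exact permutation p-values are limited to n ≤ 9; at the study's n = 18
  the t approximation is mildly anti-conservative (measured type-I error
  ≈ 0.055 at α = 0.05 in the suite's calibration test).
- MAL values are accepted as arbitrary reals in [0, 5], not snapped to the
  1/30 item grid, so tables quoted to two decimals can be ingested as-is.
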