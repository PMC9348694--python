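# Methods

This note documents the models, estimator conventions and design choices
behind `numecog`, in the spirit of a package methods appendix.  Nothing
here states an empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Stimulus model

Three run kinds are generated by `numecog.stim`:

* **Sequential numerosity runs.**  Numerosities 1–7 in an ascending sweep
  of six consecutive presentations each, twelve presentations of
  numerosity 20, a descending sweep, twelve more of 20; the whole sequence
  twice per run.  250 ms stimulus, fixed 600 ms ISI, 1.2 s grey lead-in and
  lead-out.  The bookkeeping is closed-form: with the defaults,
  216 presentations × 0.85 s + 2.4 s = **186.0 s** per run.
* **Randomized numerosity runs.**  Every numerosity exactly 24 times in a
  seeded permutation, ISI uniform on [0.65, 0.95] s.  An optional
  constraint forbids immediate repeats ("semi-randomized" is otherwise
  under-determined; the default is a plain uniform permutation).  The run
  duration is reported as computed from the drawn ISIs (about 205 s in
  expectation) and is not forced to any target value.
* **Category runs.**  12 faces, 12 letters, 12 houses in seeded random
  order; 500 ms stimulus, ISI uniform on [1.25, 1.75] s.

Oddball (white-dot attention) trials are flagged at exactly two per
numerosity by default — a deterministic reading of a ~10% oddball rate that
makes counts reproducible — with an independent-Bernoulli alternative.
Flags never alter timing, and oddball trials are not excluded from
analysis.

**Retained trials.**  In sequential runs the first presentation of each
numerosity-1–7 block is dropped (numerosity-change onset transients), and
the first *two* presentations of each numerosity-20 block.  With four
six-presentation blocks per numerosity 1–7 and four twelve-presentation
blocks of 20, this retains 20 trials per small numerosity and 40 of
numerosity 20 per run.  Dropping only one presentation of the 20-blocks
would retain 44; the drop-two rule is the default because it reproduces the
canonical 20/40 trial counts, and both counts are configurable.  Randomized
and category runs retain everything.

All onsets are seconds from run start; analysis times are seconds relative
to stimulus onset.

## Preprocessing

* **Notch.**  One zero-phase (forward–backward `filtfilt`) second-order IIR
  notch per line frequency (50, 100, 150 Hz), quality factor `f / 3 Hz`, so
  each stop band is 3 Hz wide at −3 dB.  The realization is a package
  choice; the contract is behavioral: ≥ 40 dB attenuation of a pure 50 Hz
  tone, ≤ 0.5 dB change at 30 Hz, DC untouched, near-idempotence on
  broadband input (all under test).
* **Common-average reference (CAR).**  At every sample the mean over the
  *included* channels (inclusion is always an input, mirroring clinical
  practice — the package never auto-detects bad channels) is subtracted
  from each included channel; excluded channels pass through.  CAR is a
  projection, so re-application is a no-op up to float round-off.  Note
  the well-known leakage property: each channel inherits −1/N of every
  other included channel.  On small montages this injects a visible copy of
  the montage-average response into otherwise silent channels; null
  calibrations in this package therefore use montages of a single response
  archetype.
* **Epoching.**  Pure slicing (no filtering): onset sample
  = `round_half_away(onset · fs)` plus a separately rounded trigger-offset
  shift; epoch extent is inclusive of both endpoint samples, so −0.5…+1.0 s
  at 2048 Hz gives 3073 samples.  Rounding is half-away-from-zero
  throughout.

## Spectral estimation

Per trial, channel, window centre t ∈ {−0.200, −0.190, …, +0.700} s and
frequency f ∈ {2, 4, …, 122} Hz, the estimator multiplies the 300 ms data
window centred on t (614 samples at 2048 Hz; half-open sample extent) by a
symmetric Hanning taper and evaluates the squared magnitude of the Fourier
coefficient at exactly f as a direct inner product with `exp(−2πi f t)`.
A padded-FFT grid was deliberately not used: the window's native resolution
(≈ 3.33 Hz) does not align with the 2 Hz grid, whereas direct evaluation
makes the grid exact and the independent test oracle (an explicit
direct-sum DFT) trivial.  Equivalence with that oracle is asserted to
1e-9 relative error.

* **Evoked removal** precedes power estimation: the per-condition trial
  mean is subtracted per channel and sample, so power reflects induced
  (non-phase-locked) activity.
* **Normalization** divides each frequency by its mean power over all
  retained trials and all 91 window centres, per channel and per run
  (per-run is the default scope; pooling across runs of a session is a
  config option).  The per-frequency grand mean is exactly 1 afterwards and
  the result is invariant to global rescaling of the raw voltages.
* **Baseline correction** subtracts, per trial, either the mean over
  [−0.200, −0.050] s (window mode, the default) or the value at −0.200 s
  (point mode).  Point mode exists for recordings whose trigger carried a
  fixed unknown delay: there the pre-onset window is not interpretable, so
  the single earliest grid point serves as reference and the response
  window becomes 0–0.250 s ("participant-1 mode"; the three switches are
  coupled and validated together).  Because the band average is linear,
  correcting before or after band-averaging is exactly equivalent in both
  modes; the pipeline corrects *after* so that trial QC can run on the
  uncorrected band course.
* **HFB extraction** averages the 31 bins of 60–120 Hz inclusive, and the
  per-trial scalar is the mean of that course over the response window
  (0.100–0.350 s standard, 0–0.250 s in delayed-trigger mode).  The scalar
  is recomputed from the stored course on access, so the two cannot
  disagree.

**Category runs.**  All stages are identical with category-specific
windows: epochs −0.2…+1.25 s, response window 0.100–0.350 s.  A 300 ms
sliding window centred at −0.2 s cannot fit inside an epoch that starts at
−0.2 s, so the time grid for category runs is −0.05…+1.10 s and the
baseline is the window mean over [−0.05, 0) s.  This is a package choice
forced by the geometry; trial QC (whose windows are pre-onset) is applied
to numerosity runs only.

## Trial QC

Both rules run electrode-wise on the normalized, *not yet*
baseline-corrected band course (after window-mode correction the baseline
rule would be vacuous), in a single pass, and touch only keep flags:

* **Pre-stimulus variation.**  A trial is excluded when its normalized HFB
  course varies by more than 0.5 over [−0.200, 0) s.  The default
  variation statistic is the **standard deviation** over that window; a
  max-minus-min range statistic is available by configuration.  The choice
  matters: single-trial, single-taper band power has a relative SD around
  0.3 at these settings, so the *range* of the ~20 heavily-overlapping
  pre-stimulus estimates exceeds 0.5 on a large fraction of perfectly
  clean trials (the package measures ≈ 47% on Gaussian background), which
  would turn the rule into an aggressive subsampler.  The SD reading flags
  well under 1% of clean trials — consistent with analyses of this kind
  retaining essentially all trials (e.g. 180 kept trials over 8 conditions
  yielding t-tests on 172 df) — and still fires reliably on genuine
  artifacts, so it is the default.
* **Baseline outlier.**  With `m_i` the trial's mean over
  [−0.200, −0.050] s, trial i is excluded when `|m_i − mean(m)| > 3 · sd(m)`,
  where mean and population SD pool all retained trials of that electrode
  and run regardless of condition, computed once (no re-iteration after
  removal).  On a Gaussian null this flags ≈ 0.27% (the two-sided 3σ tail;
  under test at n = 10 000).  The strict inequality makes a degenerate
  zero-SD reference flag nothing.  Note the single-pass population rule can
  *mask* when many trials are extreme simultaneously; the union with the
  variation rule covers that case.

Exclusion is monotone in both thresholds, and QC is idempotent.

## Tuning statistics

Per electrode, per-trial HFB scalars are summarized as condition means and
SEMs; the **preferred** condition is the argmax of the means (ties break to
the lower numerosity).  The tuning test is OLS with the preferred condition
as reference level and one indicator per other condition: the intercept
estimates the preferred-condition mean (its t tests response > 0 there) and
each indicator t tests that condition against the preferred one, with
residual df = N − k.  In the two-condition case the indicator t is exactly
the pooled-variance two-sample t (under test against a textbook oracle).
Per-condition p-values are uncorrected by default, matching how such
contrasts are conventionally reported; Bonferroni/Holm are available.

**Classification** uses operational thresholds (all configurable):

* `nonresponsive` — an omnibus F-test (all condition means zero) does not
  reject at α = 0.05.  The intercept t is *not* used as this gate: because
  the reference is the empirical argmax of eight noisy means, the intercept
  test is selection-biased and rejects far above its nominal level on
  silent channels, which would push the null "tuned" rate past any sensible
  bound.  The omnibus F is exact under the null.
* `tuned` — preferred numerosity below the largest level *and* at least 3
  conditions significantly below the preferred one (negative estimates,
  p < 0.05).  Preference for the smallest numerosity counts as tuned:
  contrast-energy responses must *increase* with numerosity, so only a
  preference at the largest level is energy-like.
* `energy_monotonic` — preferred = largest level and condition means
  increasing with numerosity (Spearman ρ ≥ 0.8 across levels).
* `flat_responsive` — responsive but neither of the above.

**Category comparison.**  Trials of the preferred numerosity (the default
pooling; pooling all numerosity trials is a config option) are combined
with face/letter/house trials in a second OLS with the numerosity trials as
reference; each category coefficient's t tests that category against the
preferred-numerosity response.

## Synthetic data generator

The generator (`numecog.synth`) emulates the statistical structure of a
clinical recording, not its biophysics:

* **Background**: Gaussian noise spectrally shaped to `1/f^χ` (χ = 1 by
  default) inside a 0.15–536 Hz acquisition band, standardized to SD
  `background_sd_uv` (15 µV); a fraction (0.3) of the variance is a shared
  common-mode series; sinusoidal line noise at 50/100/150 Hz (2.0 / 0.5 /
  0.25 background-SD units) rides on every channel.
* **Evoked component**: a deterministic damped 8 Hz sinusoid per
  condition (condition-specific amplitude scaling, per-channel gain drawn
  once per montage so the common-average reference does not cancel it
  exactly), identical across trials of a condition.
* **Bursts**: band-limited 60–120 Hz Gaussian noise — a broadband carrier,
  not a sinusoid, so the power gain spreads across the whole band like
  real high-frequency activity — multiplied by a trapezoidal envelope
  (onset latency 0.15 s, 0.05 s rise/fall, 0.30 s total span) and by the
  archetype amplitude with lognormal per-trial jitter (unit median,
  σ = 0.15).  The latency is chosen so that no burst energy reaches the
  sliding windows that enter the pre-stimulus QC statistics (those windows
  extend 0.15 s past their centres, the last of which sits at −0.01 s).
* **Amplitudes**: tuned channels follow
  `A(n) = A_max · exp(−(ln n − ln n_pref)²/(2σ_log²))` with defaults
  `A_max = 2.5` background-SD units and `σ_log = 0.25`; energy channels
  `A_max (n/20)^γ` with γ = 1; flat channels `A_max`; silent channels 0.
  On category trials tuned and silent channels are mute while energy and
  flat channels respond at `A_max` (numerosity-selective populations do
  not respond to faces/letters/houses; general visual populations do).
  The defaults were calibrated once, by forward power analysis, so that 20
  trials per condition yield clear but not trivial effects — the
  recovery experiment then measures what these conditions support.
* **Artifacts**: `inject_artifact_trials` adds, to a seeded exact-count
  subset of trials, a large slow half-sine plus a proportional broadband
  component over the 400 ms before onset.  The broadband part is essential:
  a purely low-frequency drift carries almost no 60–120 Hz power and would
  be invisible to a QC screen that operates on the high-frequency band,
  whereas real movement/electrode artifacts are broadband.

What the generator does **not** emulate: dipole geometry and volume
conduction, epileptiform transients, non-stationary background spectra,
channel-specific noise floors, or behavioural (oddball response) effects.
Passing recovery tests therefore demonstrates that the pipeline's
estimators and statistics are correct and well-calibrated under realistic
noise *statistics*; they cannot certify performance against pathologies the
generator does not contain.

## Recovery harness and calibration facts

`run_recovery_experiment` simulates montages of a requested archetype mix,
runs the full pipeline (notch → CAR → retention → epoch → evoked removal →
power → normalization → band average → QC → baseline → GLM → label) and
tabulates preferred-numerosity recovery and a label confusion matrix.
Montages are homogeneous in archetype because of CAR leakage (above):
mixing responsive channels into a null montage would contaminate the nulls.
The acceptance test runs 20 tuned channels for each preferred numerosity in
{1, 2, 4, 7} plus 200 silent channels and requires ≥ 90% preferred-value
recovery per group and ≤ 5% "tuned" labels among the silent channels.

## Numerical conventions

* Rounding of times to samples: half away from zero, everywhere.
* Epoch extents: inclusive of both endpoint samples; sliding-window
  extents: half-open.
* Condition ties in the argmax: lower numerosity wins (deterministic).
* SEM uses ddof = 1; the QC baseline SD uses the population convention
  (ddof = 0); the GLM is homoscedastic OLS.
* All randomness descends from one root seed via named `SeedSequence`
  substreams (plan, oddballs, noise; per-channel streams inside a run), so
  identical configurations are bit-reproducible and different montage
  sizes do not shift each other's draws.
* EDF export quantizes to 16 bits over ±3276.7 µV (0.1 µV steps) and pads
  the final one-second record with physical zero; out-of-range or
  non-finite samples are an error, never clipped.

## Known limitations

* The pipeline estimates tuning at single electrodes; it does not fit
  topographic numerosity maps or response-latency models.
* The sequential/randomized run durations other than the sequential
  186 s closed form depend on drawn ISIs and are reported, not asserted.
* The operational classification thresholds (≥ 3 significantly lower
  conditions; Spearman ρ ≥ 0.8) are reasonable defaults for 8-level
  designs with ~20 trials per condition and should be revisited for other
  designs.
* Electrode localization, clinical artifact screening and channel
  selection are inputs, never computed.
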