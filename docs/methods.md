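# Methods

This note documents the models, estimators, defaults and design choices in
`medplast`, in the spirit of a package methods appendix.  Nothing here is an
empirical claim beyond what the test suite and `scripts/acceptance.py`
compute.

## Signal model (synthetic recordings)

A sweep on channel *c* at recording time *t* (minutes) is

```
V_c(t, τ) = A(τ) − a_c(t) · f(τ − L) + ε(τ),      τ = ms within the sweep
```

* `f` is the unit-amplitude dual exponential
  `f(u) = (e^(−u/τ_d) − e^(−u/τ_r)) / f(u*)` for `u ≥ 0`, with rise
  τ_r = 1 ms, decay τ_d = 8 ms, and peak time
  `u* = τ_r τ_d/(τ_d−τ_r) · ln(τ_d/τ_r) ≈ 2.38 ms`.  The negative sign gives
  the negative-going field EPSP; the trough equals −a_c(t) exactly.
* `L = 2.5 ms` is the synaptic/conduction latency after the stimulus.
* `A` is a biphasic stimulus artifact (±200 µV, 0.4 ms total) at stimulus
  onset, identical on all channels and independent of plasticity.
* `ε` is white Gaussian noise, SD 0.25 µV per sample at 20 kHz (see
  *Noise level* below).
* Sweeps are recorded every 0.5 min: 15 min baseline (30 sweeps), then
  induction, then 60 min follow-up (120 sweeps).  Each sweep holds 6 ms of
  pre-stimulus context and 55 ms after the (last) stimulus.

**Spatial structure.**  Channels live on an 8×8 grid (150 µm pitch, 50 µm
electrodes).  Columns map to cortical compartments (default: column 0
outside, 1–3 superficial layers II–III, 4–7 deep layers V–VI); the
stimulation electrode sits at grid (3, 5) in the deep layers and records no
fEPSP itself.  Baseline amplitude decays with Euclidean grid distance *d*
from the stimulation site as `a_c = A₀ · e^(−d/λ) · e^(N(0, σ_ln))` with
A₀ = 60 µV, λ = 300 µm and log-normal channel scatter σ_ln = 0.25.  These
values were chosen once so that a slice has a realistic activated blob of
roughly 25–35 channels (> 10 µV) spanning both layers, with a rim of
near-threshold channels — the regime in which the QC rules have work to do.

**Plasticity kinetics.**  After induction at t₀ = 15 min, each
baseline-active channel's response is scaled by

```
m_c(t) = 1 + (P_c − 1) · (1 − e^(−(t−t₀)/τ_p)),    τ_p = 5 min,
```

with per-channel plateau `P_c ~ N(P_layer, 0.05)`.  The mono-exponential
form makes the mean of `m(t)` over the final 10 min equal the plateau to
within 5·10⁻⁵ relative, so the last-window statistic is an unbiased plateau
estimator and recovery is exactly testable (the discrete-time closed form is
a geometric sum the tests evaluate directly).  Channels below the activation
threshold keep their baseline amplitude: the model assigns plasticity only
to measurably activated synaptic populations, which keeps near-threshold
channels from drifting across 10 µV and masquerading as "recruitment".

**Condition presets** encode published group outcomes as generative truth
(LTP plateaus per layer, LTD plateaus, recruited-channel amplitudes and
expected counts, paired-pulse curves; the `demonstrator` preset has zero
recruitment and zero silencing).  Recruited channels are silent cells
(amplitude set to 0) drawn from the 8-neighborhood rim of the activated
area; their amplitude rises as `a(t) = A_rec · (1 − e^(−(t−t₀)/τ_p))` with
`A_rec ~ N(preset, 1 µV)`.  Silenced channels (LFS only) are activated
edge-of-blob channels whose plateau is set to 0.  Counts per slice and layer
are Poisson draws with the preset means, capped by candidate availability.
Paired-pulse sweeps superpose a second response scaled by the preset
facilitation ratio at 25/50/75/100 ms intervals.

**Noise level.**  The default trace noise is 0.25 µV SD.  This is the one
generator constant that is constrained from above by the experiment's own
rules rather than free: the baseline-stability criterion demands slope CV
< 5 % per activated channel, and the slope of a threshold-level (10 µV)
response carries a sampling-limited standard error of ≈ 0.97·σ_noise µV/ms
over the 20–80 % window.  At σ = 0.25 µV a 10 µV channel has slope CV
≈ 3.5 %, so the < 5 % rule discriminates genuinely unstable channels; at
σ ≳ 0.4 µV every near-threshold channel fails it and the > 10 % rule would
discard every slice.  The working rig that produced such recordings must
have operated in the low-noise regime, and the generator emulates that
regime.  Detection robustness is still exercised at 2 µV noise in the test
suite (activation sensitivity/specificity ≥ 0.95).

## Feature extraction

* **Artifact blanking**: samples within 1 ms after each stimulus onset are
  replaced by linear interpolation across the window.
* **Baseline reference**: mean of the 5 ms immediately pre-stimulus —
  robust to slow drift and makes all measures offset-invariant.
* **Amplitude**: the trough is located on a 1 ms boxcar-smoothed copy
  (search window 2–50 ms post-stimulus, excluding the artifact); the
  amplitude is the baseline reference minus the mean of the *raw* samples in
  a 0.25 ms window centered on the smoothed trough.  Taking the raw minimum
  of ~1000 noisy samples would overestimate silent channels by several σ;
  averaging a short window at a smoothed peak keeps the estimate within
  0.1 % of truth on noise-free input and within ~1 µV even for silent
  channels at 2 µV noise.
* **Slope**: magnitude of a least-squares line through the raw samples
  between 20 % and 80 % of peak amplitude on the initial downstroke
  (thresholds located on the smoothed trace, so the window — and hence the
  measure — is exactly scale-invariant).  Both fractions are configurable;
  20–80 % is a common field-potential convention.  Fewer than 3 samples in
  the window raises a degenerate-window error, which the table extractor
  converts to a flagged (NaN-slope) row rather than aborting the slice.
* **Paired pulses**: the first response's decay tail is fitted with
  `A·e^(−t/τ)` over the 8 ms before the second stimulus (skipped when the
  tail is within 3 SD of the noise floor) and subtracted before the second
  slope is measured against the residual inter-pulse level.  Without this,
  the 25 ms interval inflates PPR by ~3 %.

## QC operationalization

"Variation < 5 % in most active channels" is hardened into two testable
rules: per-channel stability = population CV of baseline slopes over the
final 15 min of baseline, strict `< 0.05`; slice exclusion = unstable
fraction of activated channels strictly `> 0.10` (or zero activated
channels, excluded with an explicit reason).  Activation uses the *median*
baseline amplitude (robust to a single noisy sweep) with a strict `> 10 µV`
inequality, so exactly 10.0 µV is inactive.  Stimulus calibration scans the
input–output table for the smallest intensity eliciting 40–60 % of the
maximum slope, falling back (with a warning) to the point closest to 50 %.

## Plasticity quantification and detectors

Normalized series exist only for `active_stable` channels with positive
baseline mean slope.  The last window is the final 10 min of the recording
(anchored to its end).  Channel labels use configurable thresholds —
potentiated ≥ 115 %, depressed ≤ 85 % — and both the raw per-channel means
and the labels are emitted, since published per-channel inclusion rules are
rarely stated.

Recruitment and silencing are the two directions of one threshold pair:

* recruited: baseline median ≤ 4 µV (approximately silent) **and** final
  median > 10 µV, after TBS;
* silenced: baseline median > 10 µV **and** final median ≤ 4 µV, after LFS.

The 4 µV "approximately zero" bound (rather than reusing 10 µV on both
sides) is deliberate: ordinary LTD scales a 10–15 µV channel below 10 µV
without silencing it, and ordinary LTP nudges a 9.9 µV channel above 10 µV
without recruiting anything — a single 10 µV rule mislabels both, including
in conditions where recruitment/silencing should be absent entirely.  With
the asymmetric pair, noise-free detector calls match the generative flags
exactly.

Group summaries use the **channel** as the unit of analysis (mean ± SEM over
channels pooled across a cohort's retained slices), with per-slice summaries
available.  Channels called silenced are excluded from the layer plateau
mean: a response that collapsed to ~0 µV is a silencing event reported
separately, not an LTD magnitude estimate.

## Spatial maps and statistics

Each grid cell gets exactly one category (stimulation / recruited /
silenced / plasticity / activated-only / inactive); inconsistent inputs
(e.g. a recruited channel that was baseline-active) raise naming the
channel.  Layer counts satisfy `n_with + n_without = n_active` per layer,
where silenced cells count as showing plasticity (they are maximally
depressed) and are also reported separately.  Edge detection uses
8-connectivity with the grid border counting as outside the activated set
(4-connectivity available).

Welch's t (scipy) reports the Welch–Satterthwaite df; two-way ANOVA
(statsmodels OLS, type-II sums of squares — identical to the textbook
decomposition on balanced designs) is followed by Sidak-adjusted pairwise
Welch tests or Tukey's HSD.  Zero-residual-variance designs are flagged
rather than producing an undefined F.  F-tests are one-sided on the F
distribution, which is the standard reading of a "one-tailed ANOVA".

## Numerical choices and degenerate inputs

* Voltages are stored float32 µV, times float64 minutes, indices 0-based.
* All strict inequalities at published thresholds (10 µV, 5 % CV, 10 %
  exclusion) are implemented strictly and covered by bracket tests
  (9.9/10.0/10.1 µV; 10 %/15 % unstable).
* All randomness flows from one root seed through `numpy` `SeedSequence`
  spawning (per-slice sub-streams), so identical configs reproduce outputs
  byte for byte.
* Flat traces yield amplitude 0 and a degenerate-window slope error;
  corrupt sweeps flag only their own rows.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes: grid
geometry, distance-decaying amplitudes, stable baselines, plateau kinetics,
edge-placed recruitment, paired-pulse facilitation, Gaussian noise.  It does
**not** model biophysics (no vesicle release, no NMDA/AMPA mechanism, no
TBS/LFS waveform delivery — induction is instantaneous at the end of
baseline), no line noise or drift, no electrode impedance variation, and no
between-slice plateau heterogeneity (plateau scatter is per channel only).
Passing recovery tests therefore shows that the pipeline correctly measures
what the model generates at realistic SNR and geometry — not that it is
robust to every artifact of real rigs.

## Problem sizes

Recovery runs use the cohort sizes of the emulated experiment (7/13/6 TBS
slices, 8/12 LFS slices, 150 sweeps × 64 channels per slice at 20 kHz) —
large enough that channel-pooled SEMs are a fraction of the ±2 % recovery
tolerance.  The paired-pulse check uses ≥ 500 pairs per interval.  Property
suites use reduced protocols (2 + 3 min) where duration is irrelevant.

## Known limitations

* The slope and amplitude windows are conventions; real labs differ, and
  recovered plateaus are invariant to them only because normalization
  divides the convention out.
* The PPR tail-subtraction assumes a mono-exponential tail, which is exact
  for the generator and approximate for real fEPSPs with slower components.
* The silencing/recruitment thresholds (4 µV, 10 µV) are absolute; rigs
  with very different noise floors should scale them.
* Layer assignment is by grid column; slices mounted at an angle need a
  custom `layer_of_column` map.
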