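# Methods

This note documents the models, parameter choices and numerical
decisions behind `ercpipe`, and what the synthetic-data tests do and do
not demonstrate about recorded EEG.

## Signal model and filtering

EEG is treated as a superposition of band-limited Gaussian oscillations
(Theta 3–7 Hz, Alpha 8–12 Hz, Beta 13–29 Hz, Gamma 30–69 Hz) on a 1/f
broadband background, sampled at 128 Hz in microvolts.  Band limits are
conventional; at 128 samples/s the Gamma upper edge exceeds the 64 Hz
Nyquist frequency and is capped at 0.95·Nyquist = 60.8 Hz (logged when
it bites).

Band-pass filters are linear-phase Kaiser-window FIR designs with a
fixed budget of 466 coefficients and β ≈ 5.653 (60 dB sidelobe
attenuation), one shared tap count with per-band edges.  At 128 Hz this
yields roughly a 1 Hz transition width; measured single-pass stopband
attenuation 2 Hz outside a band is ≈70 dB.  Filtering is applied
forward and backward (`y = flip(h ∗ flip(h ∗ x))`), which cancels the
232.5-sample group delay exactly and squares the magnitude response.
Edge transients are suppressed by odd-symmetric (point-reflected)
padding of length 3·(n_taps−1) before filtering; the padding is
discarded afterwards.  The implementation is verified in the tests
against a literal convolve–reverse–convolve–reverse oracle
(max |Δ| < 10⁻⁸ on 10⁴-sample signals).

The continuous recording is always filtered before segmentation, so no
filter startup transient can sit inside a 256-sample analysis window.

## Windows, band power, ERC

Each cue defines a reference window [cue−2.5 s, cue−0.5 s) and an
activity window [cue, cue+4.5 s).  Sample indices are 0-based,
windows half-open, seconds convert by floor(t·fs).  Band power over a
window is the natural log of the unbiased (n−1) sample variance — the
filtered signal's mean is near zero, but it is subtracted anyway at
negligible cost.  The log base is a convention; natural log is used
throughout.

ERC = (logvar_activity − logvar_reference) / logvar_reference.  The
ratio is undefined for |logvar_reference| ≤ 10⁻⁹ and its sign semantics
invert for negative denominators, so events with non-positive reference
log-variance are excluded and counted per reason, never silently
dropped.  In microvolt units typical log-variances are comfortably
positive (a 2 µV-RMS band gives logvar ≈ 1.4), so exclusions are rare.

Artifact handling is an automated amplitude screen: any event whose
windows contain a sample beyond a threshold (default 200 µV) is
excluded whole-trial.  This is a surrogate for manual visual
inspection, not a reconstruction of it.

## Statistical stages

* **Reaction-time trend** — OLS of reaction time on cue timestamp; the
  F-test of the regression reduces to the slope's t-test (F = t²) for a
  single regressor.  α = 0.05.
* **Idle-power trend** — per event: square the band-filtered reference
  window, smooth with a causal 128-sample (1 s) moving average, take
  logs, average to one scalar; regress the per-event values on cue
  times, F-test at α = 0.01.  Reducing each reference segment to one
  value keeps n equal to the event count and the OLS F-test well posed;
  regressing the full smoothed sample series instead would inflate n
  with strongly autocorrelated points and invalidate the test's level.
* **Dominant lobe label** — "+" ("−") when strictly more than 75% of a
  lobe's electrodes show a significant positive (negative) slope, "="
  when strictly more than 75% are not significant, else "NC".  Strict
  inequality means 6/8 does not qualify but 2/2 does; counting only
  significant slopes toward a sign makes the three rules mutually
  exclusive.
* **Power–RT correlation screen** — one-tailed Pearson test of ρ > 0
  via t = r·√((n−2)/(1−r²)), α = 0.05.  Lobe-level aggregation is
  ambiguous in principle, so both variants are computed and labelled:
  `lobe-mean` (default; correlate the lobe-averaged log power) and
  `any-electrode` (flag the lobe if any member electrode passes).
* **ERC mean test** — two-tailed one-sample t-test of mean ERC against
  zero at α = 0.05, after averaging ERC across a lobe's electrodes per
  event (one test per band × lobe).
* **Tertile ranking** — per subject, stable sort by reaction time; for
  n = 3m (+0/1/2) the group sizes are (m,m,m), (m+1,m,m), (m+1,m,m+1),
  so sizes never differ by more than one; ties break by event order.

No multiple-testing correction is applied by default: results are
reported cell by cell (16 band × lobe cells per stage), and at α = 0.05
roughly one false flag per stage per session is expected — the worked
example in the README shows exactly such a flag.  A Benjamini–Hochberg
helper (`ercpipe.stats.benjamini_hochberg`) is available.  The trend
regressions use plain OLS; no autocorrelation-robust correction is
attempted, and this limitation is inherited knowingly.

## Synthetic session generator

The generator emulates the experiment's statistical structure, not its
physiology:

* **Cue schedule** — inter-cue intervals Normal(150 s, 60 s) clamped
  below at 30 s.  Clamping (rather than conditional resampling) keeps
  the sample moments within 0.4% / 2% of the nominal mean/SD, and the
  30 s floor guarantees the 2.5 s + 4.5 s analysis windows of
  consecutive events never overlap.  The first cue must fall ≥2.5 s
  into the recording and none closer than 4.5 s to its end — late cues
  are forbidden by construction rather than truncated, since truncated
  activity windows have no defined handling in the analysis.
* **Background** — white Gaussian noise spectrally shaped to 1/f
  amplitude (flattened below 0.5 Hz), 8 µV RMS per channel.
* **Oscillations** — white noise passed through the package's own
  zero-phase band-pass filters, scaled to fixed per-band RMS (Theta 4,
  Alpha 6, Beta 3, Gamma 1.5 µV), independently per channel.  Reusing
  the tested filters guarantees in-band energy (measured ≥99% within
  the nominal band).
* **Event-locked gain** — inside each activity window, a band's
  amplitude on a lobe's channels is multiplied by `activity_gain[band,
  lobe]`; the default injects 1.5 on Theta/Frontal, the pipeline's
  canonical detectable effect.
* **Reaction times** — rt = max(rt_min, rt_base + rt_coupling·z + ε),
  with z the standardized latent frontal-Theta activity log-power and
  ε ~ N(0, rt_noise_sd²).  Defaults rt_base = 1.5 s,
  rt_coupling = 0.3 s/SD, rt_noise_sd = 0.52 s, rt_min = 0.2 s give a
  latent power–RT correlation of 0.50 and keep reaction times in a
  plausible 0.2–4 s range (the floor binds for ≈1.5% of draws).
* **Drift** — `drift_slope[band, lobe]` rescales a band component by
  (1 + slope·t/duration): a fractional amplitude change over the full
  session.  Injection after generation (`inject_amplitude_drift`)
  touches only the targeted band/lobe component, bit-identically
  preserving the rest.
* **Determinism** — one `numpy` Generator seeded from the config drives
  every draw in a fixed order; identical config + seed reproduce the
  session exactly, which the end-to-end byte-identity test relies on.

What the generator does **not** emulate: eye-blink/EMG artifacts
(beyond optional amplitude spikes injected by tests), volume
conduction and inter-channel correlation (channels are independent),
non-Gaussian and non-stationary rhythms, electrode impedance drift, or
any head-model source geometry.  Passing the recovery tests therefore
shows the pipeline detects the effects it defines, at realistic
amplitudes and sample sizes — not that those effects are detectable in
any particular recording.

## Monte Carlo scales and known limits

The acceptance-level studies run at the emulated experiment's scale:
one-hour sessions (≈24 events at 2.5-min spacing), 14 channels, 128 Hz.
Calibration studies use 10,000 null replicates (observed type-I rates
of the correlation screen, RT-trend F-test and ERC t-test all fall in
[0.04, 0.06]); the correlation-power study uses 2,000 synthetic
subjects at n = 24 (detection ≈0.81, matching the Fisher-z analytic
value); session-level recovery studies use 10 independently seeded full
sessions.

One structural limit deserves emphasis: a 2-s reference window of a
4-Hz-wide band yields a log-variance estimator with only ~2BT = 16
degrees of freedom (per-event SD ≈ 0.35), so with 24 events per session
the per-electrode idle-power trend test at α = 0.01 has little power
against moderate drift — a +50%/session amplitude drift is detected on
a given electrode only ~17% of the time, and the >75%-of-8-electrodes
"+" label essentially never fires (0/10 seeded sessions; the suite
records this as a failing expectation rather than hiding it).  Reliable
lobe-level drift detection under these window/band/event-count
constraints requires roughly a doubling of amplitude over the session
(drift ≈ 2 is detected 10/10 per electrode).  Users analysing real
sessions should treat "=" labels as "no detectable drift at this
resolution", not as evidence of stability.

## Scalp maps

Electrode → lobe grouping: AF3/AF4, F7/F8, F3/F4, FC5/FC6 frontal;
T7/T8 temporal; P7/P8 parietal; O1/O2 occipital.  2-D positions are
standard 10-10 spherical coordinates projected to the unit head circle
with exact left/right mirror symmetry, which the symmetry tests
exploit.  Rank-averaged ERC maps interpolate per-electrode means by
inverse-distance weighting (power 2) on a masked grid — deterministic
and testable, unlike renderer-internal splines; PNG rendering is an
optional CLI step on top of the exported plain-text grids.

## I/O

Recordings are read from EDF (via `mne`) or long-format CSV
(`time_s, channel, value_uV`); the simulator exports CSV (no EDF writer
is bundled).  Event tables are CSV (`event_id, cue_time_s,
response_time_s`) validated for monotone cues and positive reaction
times.  All results leave the pipeline as tidy CSVs plus a
`summary.json` whose bytes are reproducible given identical inputs,
configuration and seed.
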