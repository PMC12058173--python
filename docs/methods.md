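# Methods

## Model

The package decomposes event-locked, epoched EEG `X(c, t, n)` (channel,
time, trial) into a time-frequency representation using convolution with
complex Morlet wavelets

```
w(t, f) = A · exp(−t² / 2σt²) · exp(2iπ f t),     σt = n_cycles / (2π f)
```

A Morlet wavelet is a complex sinusoid under a Gaussian envelope; `σt` is
the envelope's temporal standard deviation and `n_cycles` expresses the
wavelet's duration in periods of its center frequency. The envelope FWHM,
`2√(2 ln 2)·σt`, is the effective temporal resolution; for a fixed cycle
count, FWHM·f is constant across the bank, so resolution in time worsens
(and in frequency improves) toward lower frequencies.

Per trial and channel the signal is cleared of its DC component (mean over
the full epoch), convolved with each wavelet, and read out as amplitude
(modulus, µV), power (squared modulus, µV²) or the raw complex
coefficients (phase accessible). Two averaging orders are supported:

- **total-induced**: transform each epoch, then average the per-trial
  amplitude/power — `avWT(c,f,t) = Σₙ X(c,f,t,n) / N`. Oscillations
  survive whether or not their phase is stimulus-locked.
- **evoked**: average the epochs into the ERP first, then transform.
  Activity with trial-varying phase cancels in the ERP (≈1/√N).

An optional across-trial standard error of the mean is carried alongside
the induced average to support descriptive "effect vs. baseline" displays.

## Normalization and unit calibration

The wavelet amplitude factor is `A = 1` (no normalization),
`A = (σt·π)^(−1/2)` (amplitude) or `A = √(2/(σt·π))` (power). For a
*normalized* bank, the transform additionally rescales each frequency's
convolution output by `2 / Σₖ|wₖ|` (twice the reciprocal L1 norm of the
wavelet's samples). This fixes the filter's passband gain: a real sinusoid
of unit amplitude at a bank frequency yields a modulus of exactly 1, at
every frequency. Consequences:

- amplitude readouts are in the signal's own units (µV) and directly
  comparable across frequencies (measured flatness across 10–90 Hz at
  500 Hz: ≤ ~1e-5 relative);
- with `normalization='none'` the raw discrete convolution is returned for
  back-compatibility with unnormalized pipelines; its scale then varies
  with frequency and is only meaningful within one frequency row.

This calibration lives in the transform rather than the wavelet samples so
that the sampled wavelets remain the closed-form expression above.

## Numerical choices

- **Support**: each wavelet is sampled on ±5σt, rounded outward to a whole
  sample, with odd length (one sample exactly at t = 0). At 5σ the
  envelope is < 4e-6 of its peak and the truncated wavelet's residual mean
  is < 1e-4 of its center sample for n_cycles ≥ 5, i.e. the wavelet's area
  is numerically zero (admissibility). A 4σ support was rejected: its
  truncation residual (~3e-3 relative) is large enough to leak DC.
- **Convolution**: FFT-based (`scipy.signal.fftconvolve`), same-length and
  center-aligned so the epoch's time axis is preserved; agreement with
  direct time-domain convolution is ~1e-15 relative on interior samples.
  The leading/trailing half-wavelet per frequency is edge-distorted and
  must be chopped (or covered by padding).
- **Edges**: the minimum padding per edge before transforming is estimated
  by the rule `t = 2000 / min(f)` ms (400 ms for a 5 Hz lower bound).
  Padding fills are `mirror` (default; value-continuous at the edge) or
  `zero`. Chopping removes an integer number of samples nearest to the
  requested milliseconds per edge and records the amount.
- **DC removal for the evoked measure** is applied to the ERP (after
  averaging); mean subtraction and averaging commute, so this only affects
  provenance.
- **Window snapping**: all time/frequency windows (baseline, statistics,
  plotting) snap endpoints to the nearest grid point and are inclusive of
  both snapped endpoints, consistently across modules.

## Baseline correction

Per channel **and per frequency** (each frequency has its own baseline
value `b`, the mean over the baseline window; default window = the full
pre-stimulus portion of the post-chop axis):

- `subtractive` (default): `v − b`. Mirrors ERP baseline correction and is
  the safer choice under an additive signal model in which oscillations and
  the broadband 1/f background contribute independently — common in
  developmental data.
- `subtractive_normalized`: `(v − b)/b`, relative change. (The name admits
  more than one formula in the literature; this package defines it as
  relative change and documents it as such.)
- `divisive`: `v / b`, assuming a multiplicative model.

Baseline correction requires an amplitude or power measure; divisive and
normalized modes refuse a zero baseline. dB conversion is
`20·log10(amplitude)` or `10·log10(power)` — the two agree for the same
underlying signal — and refuses non-positive values (as arise after
subtractive correction; correct divisively, or not at all, before dB).

## Synthetic data

The generator emulates event-locked oscillatory EEG: per trial and channel,
a sum of bursts (sinusoid under a Gaussian envelope whose `duration` is its
FWHM, or a boxcar) plus Gaussian noise, optionally spectrally shaped to
1/f^α. `phase_policy='locked'` fixes the burst phase across trials
(evoked + induced); `'jittered'` draws a uniform phase per trial (induced
only; cancels in the ERP as ≈1/√N). An integer seed fully determines the
output.

The tutorial-like fixture set emulates a 2×2 infant paradigm
(Modality × Ostension): 3 subjects × 4 conditions (DG = direct gaze,
AG = averted gaze, IDS/ADS = infant-/adult-directed speech) × 12 trials ×
19 channels at 500 Hz, epochs −500..+1500 ms (1001 samples). DG carries a
phase-locked 35 Hz frontal burst at 300 ms, amplitude 3 µV over noise
SD 1 µV (amplitude SNR 3); AG carries none; the speech conditions carry
weaker jittered 15 Hz temporal bursts. These sizes keep the default test
suite and the reproduction script comfortably fast while leaving the
burst clearly supra-threshold.

What the generator does **not** emulate: volume conduction and realistic
cross-channel covariance, artifacts (blinks, motion), non-stationary
background spectra, inter-subject variability of burst frequency/latency.
Passing tests therefore demonstrate correctness of the signal-processing
chain on controlled oscillatory content, not robustness to real infant EEG
recording conditions.

## File formats

- `plain_matrix`: HDF5 with datasets `data` (trials × channels × samples),
  `time_ms`, `channels`, `fs`, plus `condition`/`subject` attributes.
- EEGLAB `.set` (read): MATLAB-v5 `EEG` struct, inline data or sibling
  `.fdt` (float32, column-major). Only one-trigger-per-epoch designs are
  accepted; multiple events in an epoch raise an error rather than guess.
- WT container: MATLAB-v5 file with the Channel × Frequency × Time tensor
  under the variable `WT` and axes `Fa` (Hz) / `tim` (ms), following the
  ERPWAVELAB data structure; package provenance (measure, labels, baseline,
  chopping, SEM) is namespaced under `wtf_meta`/`wtf_sem` to avoid
  collisions with fields other tools may define.
- Statistics export: tab-separated text, rows = subjects, columns =
  condition-major × channel (`condition_channel` headers), `%.17g` floats
  with `.` decimal separator (locale-independent); parse-back agrees to
  ≥ 15 significant digits.

## Visualization

Time-frequency rasters use a sequential colormap for raw amplitude/power
and a zero-symmetric diverging map for baseline-corrected data and
condition differences. The optional SEM display contours |value| = SEM, a
descriptive (not inferential) outline. Scalp maps reduce the tensor to one
scalar per channel using exactly the statistics-export window mean
(single-point windows for point selections), interpolate with a thin-plate
(biharmonic) spline over unit-disc electrode positions, and mask beyond
the electrode convex hull plus a 12% margin; extrapolation beyond that is
deliberately not shown. `.ced` (EEGLAB polar) and `.sfp`-style Cartesian
layout files are parsed and normalized to the unit disc (nose +y).

## Known limitations

- Inter-trial phase coherence / phase-locking statistics and
  cross-frequency coupling are out of scope (the complex measure exposes
  the phases for downstream use).
- No statistical inference: the export table is input for third-party
  statistics packages.
- The divisive baseline accepts either amplitude or power input; choosing
  which is scientifically appropriate is left to the user.
- EEGLAB `.set` reading covers the common epoched layout; exotic variants
  (per-epoch event tables only, boundary events) are rejected, not
  interpreted.
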