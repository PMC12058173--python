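# wavelet-tf

Complex Morlet wavelet time-frequency analysis for event-locked, epoched
EEG, aimed at developmental/cognitive electrophysiology pipelines where
induced (non-phase-locked) oscillations matter as much as evoked activity.
It provides a scriptable library plus a `wavelet-tf` command line covering
the full chain: wavelet-bank construction, per-trial continuous wavelet
transform, total-induced and evoked measures, edge padding/chopping, three
baseline-correction modes, ERPWAVELAB-compatible `WT` containers,
window-averaged statistics export, and time-frequency / scalp-map plots —
all testable on synthetic data with known oscillatory content.

## The method

Epoched EEG `X(c, t, n)` is convolved per trial (after DC removal) with a
bank of complex Morlet wavelets

    w(t, f) = A · exp(−t²/2σt²) · exp(2iπft),   σt = n_cycles/(2πf)

with `n_cycles = 7` by default. The modulus of the complex coefficients
gives amplitude in µV (power and raw complex coefficients are also
available). Averaging order selects the measure:

- **total-induced**: `avWT(c,f,t) = Σₙ X(c,f,t,n)/N` — transform each
  epoch, then average; preserves oscillations regardless of phase locking;
- **evoked**: transform the across-trial average (ERP); non-phase-locked
  activity cancels first (≈1/√N).

Normalized banks are gain-calibrated so a unit-amplitude sinusoid yields
amplitude 1 at every bank frequency — frequency content is directly
comparable across frequencies and stays in signal units. Convolution-
distorted edges are chopped (`2000/min(f)` ms per edge is the recommended
padding rule of thumb), and baseline correction is per channel *and* per
frequency, subtractive by default (`v − b`, ERP-style), with
`(v − b)/b` and `v/b` as options. See `docs/methods.md` for the details
and the reasoning behind each convention.

## Worked example

Generate a synthetic "direct gaze" dataset from the tutorial-like fixture
(12 trials × 19 channels at 500 Hz, epochs −500..+1500 ms, with a
phase-locked 35 Hz frontal burst at 300 ms riding on unit noise), run the
default pipeline, and query the frontal gamma window:

```python
import numpy as np, wavelet_tf as wt
from wavelet_tf.synthetic import tutorial_spec

ep = wt.generate(tutorial_spec("DG", "01", seed=0))
print("epochs:", ep.data.shape, "fs =", ep.sampling_rate, "Hz,",
      f"{ep.time_ms[0]:.0f}..{ep.time_ms[-1]:.0f} ms")

res = wt.analyze_epochs(ep, wt.AnalysisParams())   # 10-90 Hz, 7 cycles,
print("WT:", res.values.shape, "(channel x frequency x time),",  # chop 300 ms,
      f"{res.time_ms[0]:.0f}..{res.time_ms[-1]:.0f} ms after 300 ms chopping")
                                                   # subtractive baseline
frontal = wt.average_channels(res, ["Fp1", "Fpz", "Fp2"])
v = wt.window_mean(frontal, (250, 350), (30, 40), frontal.channel_labels[0])
print(f"frontal 250-350 ms x 30-40 Hz mean: {v:.3f} uV above baseline")
fi, ti = np.unravel_index(np.argmax(frontal.values[0]), frontal.values[0].shape)
print(f"peak at {frontal.frequencies[fi]:.0f} Hz, {frontal.time_ms[ti]:.0f} ms")
```

prints

```
epochs: (12, 19, 1001) fs = 500.0 Hz, -500..1500 ms
WT: (19, 81, 701) (channel x frequency x time), -200..1200 ms after 300 ms chopping
frontal 250-350 ms x 30-40 Hz mean: 1.754 uV above baseline
peak at 35 Hz, 300 ms
```

The transform recovers the injected burst at its true frequency and
latency, and the window-averaged amplitude (~1.75 µV above the
pre-stimulus baseline) is the quantity the statistics export writes per
subject × condition × channel for third-party analysis.

The same flow from a shell:

```sh
wavelet-tf synth --kind tutorial --seed 7 --out proj      # fixtures + config
wavelet-tf project run --config proj/project.yaml          # 12 WT files
wavelet-tf export --config proj/project.yaml \
    --time 250,350 --freq 30,40 --channels Fp1+Fpz+Fp2     # Statistics/export.tab
wavelet-tf plot tf   --input proj/wt/01_DG.wt.mat --channel Fp2 --output dg.png
```

## Layout

| Module | Role |
| --- | --- |
| `wavelet_tf.wavelets` | Morlet banks, σt/FWHM, padding rule, bank summary |
| `wavelet_tf.transform` | CWT, total-induced / evoked averaging, SEM |
| `wavelet_tf.adjust` | chop, pad, baseline modes, dB, channel averages |
| `wavelet_tf.io_project` | `.set`/HDF5 readers, WT containers, batch runs |
| `wavelet_tf.stats_export` | window means, `.tab` statistics tables |
| `wavelet_tf.viz` | TF rasters, condition differences, 2D scalp maps |
| `wavelet_tf.synthetic` | seeded burst + noise generator, fixture sets |
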