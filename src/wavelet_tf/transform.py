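"""Continuous wavelet transform of epoched EEG and trial averaging.

Each epoch is cleared of its DC component, convolved per frequency with a
complex Morlet wavelet, and read out as amplitude (modulus of the complex
coefficients), power (squared modulus) or the raw complex coefficients.

Two averaging orders give the two classical measures:

* **total-induced** — transform every epoch, then average the per-trial
  amplitude/power across trials (``avWT(c,f,t) = sum_n X(c,f,t,n) / N``).
  Oscillatory activity survives whether or not its phase is locked to
  stimulus onset.
* **evoked** — average the epochs first (the ERP), then transform the
  average.  Activity whose phase varies from trial to trial cancels in the
  ERP (roughly as 1/sqrt(N)) before it can reach the transform.

Unit calibration
----------------
For a normalized bank (``amplitude`` or ``power`` normalization), the
convolution output at each frequency is rescaled by ``2 / sum_k |w_k|``
(twice the reciprocal L1 norm of that wavelet's samples).  This fixes the
filter's passband gain so that a real sinusoid of unit amplitude at a bank
frequency yields a modulus of 1 at that frequency — i.e. amplitude readouts
are in the signal's own units (microvolts) and are directly comparable
across frequencies, which is the point of wavelet normalization.  With
``normalization='none'`` the raw discrete convolution is returned for
back-compatibility with unnormalized pipelines; its scale then varies with
frequency.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .containers import EpochedData, TFResult
from .errors import InvalidParameterError, SignalTooShortError
from .wavelets import WaveletBank

_TRANSFORM_MEASURES = ("amplitude", "power", "complex")


def remove_dc(epochs: EpochedData) -> EpochedData:
    """Subtract each (trial, channel) trace's mean over the full epoch extent."""
    data = epochs.data - epochs.data.mean(axis=-1, keepdims=True)
    return epochs.copy_with(data=data)


def _gains(bank: WaveletBank) -> np.ndarray:
    """Per-frequency scaling applied to the raw discrete convolution."""
    if bank.spec.normalization == "none":
        return np.ones(len(bank.wavelets))
    return np.array([2.0 / np.sum(np.abs(w)) for w in bank.wavelets])


def _check_length(n_samples: int, bank: WaveletBank):
    for f, w in zip(bank.spec.frequencies, bank.wavelets):
        if n_samples < len(w):
            raise SignalTooShortError(
                f"signal of {n_samples} samples is shorter than the "
                f"{len(w)}-sample wavelet at {f} Hz; provide a longer or "
                f"padded segment"
            )


def _cwt_block(traces: np.ndarray, bank: WaveletBank) -> np.ndarray:
    """CWT of a (..., n_samples) block -> (n_freq, ..., n_samples) complex.

    Output is same-length and center-aligned: coefficient k corresponds to
    the wavelet centered on input sample k.  The leading/trailing
    ``(len(wavelet)-1)//2`` samples per frequency are edge-distorted and
    should be removed by chopping.
    """
    _check_length(traces.shape[-1], bank)
    gains = _gains(bank)
    out = np.empty((len(bank.wavelets),) + traces.shape, dtype=np.complex128)
    shape1 = (1,) * (traces.ndim - 1)
    for i, (w, g) in enumerate(zip(bank.wavelets, gains)):
        kernel = w.reshape(shape1 + (len(w),))
        out[i] = g * fftconvolve(traces, kernel, mode="same", axes=-1)
    return out


def cwt_single(trace: np.ndarray, bank: WaveletBank) -> np.ndarray:
    """Complex wavelet coefficients (frequency x time) of one trace.

    Raises
    ------
    SignalTooShortError
        If the trace is shorter than the longest (lowest-frequency) wavelet.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1:
        raise InvalidParameterError(f"trace must be 1-D, got shape {trace.shape}")
    return _cwt_block(trace, bank)


def _resolve_subset(n_trials: int, trial_subset: Optional[Sequence[int]]) -> np.ndarray:
    if trial_subset is None:
        return np.arange(n_trials)
    idx = np.asarray(list(trial_subset), dtype=int)
    if idx.size == 0:
        raise InvalidParameterError("trial_subset must not be empty")
    if np.any(idx < 0) or np.any(idx >= n_trials):
        raise InvalidParameterError(
            f"trial_subset indices must lie in [0, {n_trials}); got {idx.tolist()}"
        )
    return idx


def _apply_measure(coeffs: np.ndarray, measure: str) -> np.ndarray:
    if measure == "amplitude":
        return np.abs(coeffs)
    if measure == "power":
        return np.abs(coeffs) ** 2
    return coeffs


def transform_total_induced(
    epochs: EpochedData,
    bank: WaveletBank,
    measure: str = "amplitude",
    trial_subset: Optional[Sequence[int]] = None,
    compute_sem: bool = False,
) -> TFResult:
    """Total-induced time-frequency measure: transform each trial, then average.

    Parameters
    ----------
    epochs
        Epoched data; DC is removed per trial and channel before transforming.
    bank
        Wavelet bank discretized at ``epochs.sampling_rate``.
    measure
        'amplitude' (default), 'power', or 'complex' (defers the modulus so
        phase can be extracted; note averaging complex coefficients across
        trials cancels non-phase-locked activity).
    trial_subset
        Optional trial indices to restrict the average (single-trial
        extraction with a one-element subset).
    compute_sem
        Also estimate the across-trial standard error of the mean (not
        available for the complex measure), stored on ``TFResult.sem``.
    """
    if measure not in _TRANSFORM_MEASURES:
        raise InvalidParameterError(
            f"measure must be one of {_TRANSFORM_MEASURES}, got {measure!r}"
        )
    if abs(bank.spec.sampling_rate - epochs.sampling_rate) > 1e-6:
        raise InvalidParameterError(
            f"bank sampling rate {bank.spec.sampling_rate} != data rate "
            f"{epochs.sampling_rate}"
        )
    if compute_sem and measure == "complex":
        raise InvalidParameterError("SEM is not defined for the complex measure")
    idx = _resolve_subset(epochs.n_trials, trial_subset)
    clean = remove_dc(epochs)
    n = len(idx)
    n_ch, n_s = epochs.n_channels, epochs.n_samples
    n_f = len(bank.wavelets)
    dtype = np.complex128 if measure == "complex" else np.float64
    acc = np.zeros((n_ch, n_f, n_s), dtype=dtype)
    acc2 = np.zeros((n_ch, n_f, n_s)) if compute_sem else None
    # One trial at a time keeps peak memory at (n_freq x n_ch x n_samples).
    for t in idx:
        coeffs = _cwt_block(clean.data[t], bank)  # (n_f, n_ch, n_s)
        x = _apply_measure(coeffs, measure).transpose(1, 0, 2)
        acc += x
        if compute_sem:
            acc2 += x**2
    mean = acc / n
    sem = None
    if compute_sem:
        if n > 1:
            var = np.maximum(acc2 / n - np.abs(mean) ** 2, 0.0) * (n / (n - 1))
            sem = np.sqrt(var / n)
        else:
            sem = np.zeros_like(acc2)
    return TFResult(
        values=mean,
        measure=measure,
        frequencies=bank.frequencies,
        time_ms=epochs.time_ms,
        channel_labels=list(epochs.channel_labels),
        n_trials_averaged=n,
        condition=epochs.condition,
        subject=epochs.subject,
        sem=sem,
    )


def transform_evoked(
    epochs: EpochedData,
    bank: WaveletBank,
    measure: str = "amplitude",
    trial_subset: Optional[Sequence[int]] = None,
) -> TFResult:
    """Evoked time-frequency measure: average the trials (ERP), then transform.

    DC removal is applied to the ERP (after averaging); averaging and mean
    subtraction commute, so the order only matters for provenance.
    ``n_trials_averaged`` records the number of trials entering the ERP.
    """
    if measure not in _TRANSFORM_MEASURES:
        raise InvalidParameterError(
            f"measure must be one of {_TRANSFORM_MEASURES}, got {measure!r}"
        )
    idx = _resolve_subset(epochs.n_trials, trial_subset)
    erp = epochs.data[idx].mean(axis=0)  # (n_ch, n_s)
    erp = erp - erp.mean(axis=-1, keepdims=True)
    coeffs = _cwt_block(erp, bank).transpose(1, 0, 2)
    return TFResult(
        values=_apply_measure(coeffs, measure),
        measure=measure,
        frequencies=bank.frequencies,
        time_ms=epochs.time_ms,
        channel_labels=list(epochs.channel_labels),
        n_trials_averaged=len(idx),
        condition=epochs.condition,
        subject=epochs.subject,
    )
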