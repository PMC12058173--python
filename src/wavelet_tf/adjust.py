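"""Post-transform adjustments: edge handling, baseline correction, dB, channel averages.

Edge chopping removes the convolution-distorted samples at segment
boundaries; optional edge padding extends the raw epochs beforehand so that
the distortion falls on synthetic signal that is chopped away afterwards.

Baseline correction is per channel AND per frequency — each frequency has
its own baseline value ``b`` (mean over the baseline window):

* ``subtractive`` (default): value - b.  Analogous to ERP baseline
  correction; appropriate under an additive signal model, which is the
  safer assumption when signal and broadband 1/f background contribute
  independently (common in developmental data).
* ``subtractive_normalized``: (value - b) / b, relative change.
* ``divisive``: value / b, assuming a multiplicative model in which
  oscillations and 1/f background scale together.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .containers import EpochedData, TFResult
from .errors import (
    DegenerateBaselineError,
    DomainError,
    InvalidParameterError,
    UnsupportedMeasureError,
)

BASELINE_MODES = ("none", "subtractive", "subtractive_normalized", "divisive")


@dataclass(frozen=True)
class BaselineSpec:
    """Baseline-correction mode plus time window [start_ms, end_ms].

    Window endpoints snap to the nearest sample of the result's time axis
    and are inclusive after snapping.  ``window=None`` means the full
    pre-stimulus portion of the axis (the default pipeline's choice).
    """

    mode: str = "subtractive"
    window: Tuple[float, float] = None

    def __post_init__(self):
        if self.mode not in BASELINE_MODES:
            raise InvalidParameterError(
                f"baseline mode must be one of {BASELINE_MODES}, got {self.mode!r}"
            )
        if self.window is not None:
            start, end = self.window
            if not start < end:
                raise InvalidParameterError(
                    f"baseline window must satisfy start < end, got {self.window}"
                )
            object.__setattr__(self, "window", (float(start), float(end)))


def snap_window(axis: np.ndarray, window: Sequence[float], name: str = "window"):
    """Snap [lo, hi] to nearest grid points of ``axis``; return (ilo, ihi) inclusive."""
    lo, hi = float(window[0]), float(window[1])
    if lo > hi:
        raise InvalidParameterError(f"{name}: start {lo} > end {hi}")
    amin, amax = float(axis[0]), float(axis[-1])
    half = 0.5 * float(axis[1] - axis[0]) if len(axis) > 1 else 0.0
    if lo < amin - half or hi > amax + half:
        raise InvalidParameterError(
            f"{name} [{lo}, {hi}] outside valid range [{amin}, {amax}]"
        )
    ilo = int(np.argmin(np.abs(axis - lo)))
    ihi = int(np.argmin(np.abs(axis - hi)))
    return ilo, ihi


def chop_edges(result: TFResult, per_edge_ms: float) -> TFResult:
    """Remove ``per_edge_ms`` from each end of the time axis.

    The removed duration absorbs the convolution edge distortion; e.g. an
    epoch spanning -500..+1500 ms chopped by 300 ms per edge leaves a
    1400 ms segment spanning -200..+1200 ms.
    """
    if per_edge_ms < 0:
        raise InvalidParameterError(f"per_edge_ms must be >= 0, got {per_edge_ms}")
    if per_edge_ms == 0:
        return result
    dt = float(result.time_ms[1] - result.time_ms[0])
    n = int(round(per_edge_ms / dt))
    duration = float(result.time_ms[-1] - result.time_ms[0])
    if 2 * per_edge_ms >= duration:
        raise InvalidParameterError(
            f"cannot chop 2 x {per_edge_ms} ms from a {duration} ms segment"
        )
    removed = n * dt
    out = result.copy_with(
        values=result.values[:, :, n : result.values.shape[2] - n].copy(),
        time_ms=result.time_ms[n : len(result.time_ms) - n].copy(),
        chopped_ms=result.chopped_ms + removed,
        sem=None
        if result.sem is None
        else result.sem[:, :, n : result.sem.shape[2] - n].copy(),
    )
    return out


def pad_edges(
    epochs: EpochedData, per_edge_ms: float, method: str = "mirror"
) -> EpochedData:
    """Extend each epoch by ``per_edge_ms`` of synthetic signal per edge.

    ``method='mirror'`` reflects the signal about each end point (value
    continuity at the edge, the default); ``'zero'`` pads with zeros.  The
    padding duration is recorded on ``padded_ms`` so it can be chopped off
    after transformation.
    """
    if per_edge_ms < 0:
        raise InvalidParameterError(f"per_edge_ms must be >= 0, got {per_edge_ms}")
    if method not in ("zero", "mirror"):
        raise InvalidParameterError(f"method must be 'zero' or 'mirror', got {method!r}")
    n = int(round(per_edge_ms * epochs.sampling_rate / 1000.0))
    if n == 0:
        return epochs
    if method == "zero":
        data = np.pad(epochs.data, ((0, 0), (0, 0), (n, n)), mode="constant")
    else:
        if n >= epochs.n_samples:
            raise InvalidParameterError(
                f"mirror padding of {n} samples needs an epoch longer than {n} samples"
            )
        data = np.pad(epochs.data, ((0, 0), (0, 0), (n, n)), mode="reflect")
    dt = 1000.0 / epochs.sampling_rate
    pre = epochs.time_ms[0] - dt * np.arange(n, 0, -1)
    post = epochs.time_ms[-1] + dt * np.arange(1, n + 1)
    time_ms = np.concatenate([pre, epochs.time_ms, post])
    return epochs.copy_with(
        data=data, time_ms=time_ms, padded_ms=epochs.padded_ms + n * dt
    )


def default_baseline_window(result: TFResult) -> Tuple[float, float]:
    """Full pre-stimulus portion [t_min, 0] of the result's time axis."""
    if result.time_ms[0] >= 0:
        raise InvalidParameterError(
            "no pre-stimulus samples available for a default baseline window"
        )
    return (float(result.time_ms[0]), 0.0)


def baseline_correct(result: TFResult, spec: BaselineSpec) -> TFResult:
    """Apply per-(channel, frequency) baseline correction.

    Raises
    ------
    UnsupportedMeasureError
        For complex or dB inputs (correct before converting to dB).
    DegenerateBaselineError
        When a divisive/normalized baseline value is zero.
    """
    if spec.mode == "none":
        return result.copy_with(baseline=spec)
    if result.measure not in ("amplitude", "power"):
        raise UnsupportedMeasureError(
            f"baseline correction requires an amplitude or power result, "
            f"got measure {result.measure!r}"
        )
    window = spec.window if spec.window is not None else default_baseline_window(result)
    ilo, ihi = snap_window(result.time_ms, window, name="baseline window")
    b = result.values[:, :, ilo : ihi + 1].mean(axis=-1, keepdims=True)
    if spec.mode == "subtractive":
        values = result.values - b
    else:
        if np.any(b == 0):
            raise DegenerateBaselineError(
                f"{spec.mode} baseline undefined: zero baseline value in window "
                f"[{window[0]}, {window[1]}] ms"
            )
        values = result.values / b - (1.0 if spec.mode == "subtractive_normalized" else 0.0)
    return result.copy_with(values=values, baseline=spec)


def to_db(result: TFResult) -> TFResult:
    """Convert amplitude (20 log10) or power (10 log10) to decibels.

    The two conventions agree for the same underlying signal
    (20 log10 a == 10 log10 a^2).

    Raises
    ------
    DomainError
        If any value is <= 0 (e.g. after subtractive baseline correction);
        use a divisive baseline, or none, before converting to dB.
    """
    if result.measure not in ("amplitude", "power"):
        raise UnsupportedMeasureError(
            f"dB conversion requires amplitude or power, got {result.measure!r}"
        )
    if np.any(result.values <= 0):
        raise DomainError(
            "dB conversion requires strictly positive values; subtractively "
            "baseline-corrected data can be <= 0 — use a divisive baseline "
            "(or no correction) before converting to dB"
        )
    factor = 20.0 if result.measure == "amplitude" else 10.0
    return result.copy_with(
        values=factor * np.log10(result.values), measure="dB", sem=None
    )


def average_channels(result: TFResult, subset: Sequence[str]) -> TFResult:
    """Unweighted mean over a subset of channels -> single-channel result.

    The output channel label records the membership, e.g. ``avg(C3+Cz+C4)``.
    """
    subset = [str(s) for s in subset]
    if len(subset) == 0:
        raise InvalidParameterError("channel subset must not be empty")
    unknown = [s for s in subset if s not in result.channel_labels]
    if unknown:
        raise InvalidParameterError(
            f"unknown channel label(s) {unknown}; available: {result.channel_labels}"
        )
    idx = [result.channel_labels.index(s) for s in subset]
    values = result.values[idx].mean(axis=0, keepdims=True)
    sem = None if result.sem is None else result.sem[idx].mean(axis=0, keepdims=True)
    label = "avg(" + "+".join(subset) + ")" if len(subset) > 1 else subset[0]
    return result.copy_with(values=values, channel_labels=[label], sem=sem)
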