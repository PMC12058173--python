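"""In-memory containers shared across the pipeline.

:class:`EpochedData` holds event-locked EEG epochs as a
(trial, channel, sample) tensor with a millisecond time axis anchored at
stimulus onset.  :class:`TFResult` holds a transformed
(channel, frequency, time) tensor — the "WT" layout of the ERPWAVELAB
ecosystem — together with the provenance needed to interpret it (measure,
trials averaged, baseline, edge chopping).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidParameterError

#: Valid measures for a TFResult.
MEASURES = ("complex", "amplitude", "power", "dB")


@dataclass
class EpochedData:
    """Epoched multi-channel EEG.

    Parameters
    ----------
    data
        Array of shape (n_trials, n_channels, n_samples), in signal units
        (conventionally microvolts).
    sampling_rate
        Hz.
    time_ms
        Time axis in milliseconds relative to stimulus onset; uniform
        spacing of 1000 / sampling_rate; onset (t = 0) present or bracketed.
    channel_labels
        One identifier per channel.
    condition, subject
        Optional provenance labels.
    padded_ms
        Milliseconds of synthetic signal added per edge by
        :func:`wavelet_tf.adjust.pad_edges` (0 for raw data).
    """

    data: np.ndarray
    sampling_rate: float
    time_ms: np.ndarray
    channel_labels: list
    condition: Optional[str] = None
    subject: Optional[str] = None
    padded_ms: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.time_ms = np.asarray(self.time_ms, dtype=np.float64)
        self.channel_labels = [str(c) for c in self.channel_labels]
        if self.data.ndim != 3:
            raise InvalidParameterError(
                f"data must be (trials, channels, samples); got shape {self.data.shape}"
            )
        n_tr, n_ch, n_s = self.data.shape
        if n_tr < 1 or n_ch < 1:
            raise InvalidParameterError("need at least 1 trial and 1 channel")
        if len(self.channel_labels) != n_ch:
            raise InvalidParameterError(
                f"{len(self.channel_labels)} channel labels for {n_ch} channels"
            )
        if self.time_ms.shape != (n_s,):
            raise InvalidParameterError(
                f"time axis length {self.time_ms.shape} does not match {n_s} samples"
            )
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be > 0")
        step = 1000.0 / self.sampling_rate
        if n_s > 1 and not np.allclose(np.diff(self.time_ms), step, rtol=1e-6, atol=1e-6):
            raise InvalidParameterError(
                f"time axis spacing must equal 1000/fs = {step} ms"
            )
        if not np.all(np.isfinite(self.data)):
            raise InvalidParameterError("data contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy_with(self, **changes) -> "EpochedData":
        return replace(self, **changes)


@dataclass
class TFResult:
    """Time-frequency decomposition of epoched EEG.

    ``values`` is (channel, frequency, time).  For ``measure='amplitude'``
    values are in signal units (microvolts, when wavelets are normalized),
    for ``'power'`` squared signal units, ``'complex'`` retains the raw
    coefficients (phase accessible), and ``'dB'`` is a log-scaled display
    measure.  ``sem`` optionally carries the across-trial standard error of
    the mean of the same quantity, same shape as ``values``.
    """

    values: np.ndarray
    measure: str
    frequencies: np.ndarray
    time_ms: np.ndarray
    channel_labels: list
    n_trials_averaged: int = 1
    baseline: Optional[object] = None  # BaselineSpec, kept loose to avoid cycle
    chopped_ms: float = 0.0
    condition: Optional[str] = None
    subject: Optional[str] = None
    sem: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        if self.measure not in MEASURES:
            raise InvalidParameterError(
                f"measure must be one of {MEASURES}, got {self.measure!r}"
            )
        dtype = np.complex128 if self.measure == "complex" else np.float64
        self.values = np.asarray(self.values, dtype=dtype)
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        self.time_ms = np.asarray(self.time_ms, dtype=np.float64)
        self.channel_labels = [str(c) for c in self.channel_labels]
        if self.values.ndim != 3:
            raise InvalidParameterError(
                f"values must be (channel, frequency, time); got shape {self.values.shape}"
            )
        n_ch, n_f, n_t = self.values.shape
        if len(self.channel_labels) != n_ch:
            raise InvalidParameterError(
                f"{len(self.channel_labels)} channel labels for {n_ch} channels"
            )
        if self.frequencies.shape != (n_f,):
            raise InvalidParameterError("frequency axis does not match values")
        if self.time_ms.shape != (n_t,):
            raise InvalidParameterError("time axis does not match values")
        # No sign constraint here: the transform layer produces non-negative
        # amplitude/power by construction, but baseline-corrected values and
        # condition differences legitimately go negative.
        if self.measure != "complex" and not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("values contain non-finite entries")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=np.float64)
            if self.sem.shape != self.values.shape:
                raise InvalidParameterError("sem shape must match values")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def sampling_rate(self) -> float:
        if len(self.time_ms) < 2:
            raise InvalidParameterError("cannot infer sampling rate from a single sample")
        return 1000.0 / float(self.time_ms[1] - self.time_ms[0])

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(str(label))
        except ValueError:
            raise InvalidParameterError(
                f"unknown channel {label!r}; available: {self.channel_labels}"
            ) from None

    def copy_with(self, **changes) -> "TFResult":
        return replace(self, **changes)


def check_compatible(a: TFResult, b: TFResult, *, context: str = "operation"):
    """Raise IncompatibleResultsError unless a and b share axes, labels and measure."""
    from .errors import IncompatibleResultsError

    problems = []
    if a.measure != b.measure:
        problems.append(f"measure {a.measure!r} vs {b.measure!r}")
    if a.channel_labels != b.channel_labels:
        problems.append("channel labels differ")
    if a.frequencies.shape != b.frequencies.shape or not np.allclose(
        a.frequencies, b.frequencies
    ):
        problems.append("frequency axes differ")
    if a.time_ms.shape != b.time_ms.shape or not np.allclose(a.time_ms, b.time_ms):
        problems.append("time axes differ")
    if problems:
        raise IncompatibleResultsError(f"{context}: " + "; ".join(problems))
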