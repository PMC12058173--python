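"""Synthetic epoched EEG with known oscillatory content.

Generates trials x channels x samples tensors containing oscillatory bursts
(controlled frequency, latency, duration, amplitude, and per-trial phase
policy) on top of Gaussian broadband noise, optionally spectrally shaped to
1/f^alpha.  A burst with ``phase_policy='locked'`` has the same phase on
every trial (it survives ERP averaging, i.e. it is *evoked*); with
``'jittered'`` its phase is drawn uniformly per trial (it cancels in the
ERP roughly as 1/sqrt(N) but survives per-trial amplitude averaging, i.e.
it is *induced only*).

Everything is driven by an integer seed: identical seeds give bitwise
identical data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np

from .containers import EpochedData
from .errors import InvalidParameterError

_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Default channel montage for multi-channel fixtures (10-20 labels).
DEFAULT_MONTAGE = (
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8", "P7", "P3", "Pz", "P4", "P8", "Oz",
)


@dataclass(frozen=True)
class BurstSpec:
    """One oscillatory burst injected into every trial.

    Parameters
    ----------
    frequency
        Oscillation frequency (Hz); must lie below the target Nyquist.
    center_latency_ms
        Envelope center relative to stimulus onset.
    duration_ms
        Envelope width.  For the default Gaussian envelope this is its FWHM
        (so "duration" lines up with the wavelet-resolution vocabulary);
        for ``envelope='boxcar'`` it is the full width.
    amplitude
        Peak amplitude in signal units (microvolts).
    phase_policy
        'locked' (fixed ``phase`` every trial) or 'jittered' (uniform random
        phase per trial).
    phase
        Phase (rad) used when locked.
    channels
        Labels receiving the burst; None = all channels.
    """

    frequency: float
    center_latency_ms: float = 300.0
    duration_ms: float = 100.0
    amplitude: float = 1.0
    phase_policy: str = "locked"
    phase: float = 0.0
    envelope: str = "gaussian"
    channels: Optional[Tuple[str, ...]] = None

    def __post_init__(self):
        if self.frequency <= 0:
            raise InvalidParameterError("burst frequency must be > 0")
        if self.duration_ms <= 0:
            raise InvalidParameterError("burst duration must be > 0")
        if self.amplitude < 0:
            raise InvalidParameterError("burst amplitude must be >= 0")
        if self.phase_policy not in ("locked", "jittered"):
            raise InvalidParameterError(
                f"phase_policy must be 'locked' or 'jittered', got {self.phase_policy!r}"
            )
        if self.envelope not in ("gaussian", "boxcar"):
            raise InvalidParameterError(
                f"envelope must be 'gaussian' or 'boxcar', got {self.envelope!r}"
            )
        if self.channels is not None:
            object.__setattr__(self, "channels", tuple(str(c) for c in self.channels))


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic epoched dataset.

    ``epoch_window_ms`` must bracket stimulus onset (t = 0).  ``noise_sd``
    is the per-sample SD of the broadband noise; ``noise_alpha`` > 0 shapes
    its spectrum to 1/f^alpha (0 = white).  The seed fully determines the
    output.
    """

    n_trials: int = 20
    n_channels: int = 4
    sampling_rate: float = 500.0
    epoch_window_ms: Tuple[float, float] = (-500.0, 1500.0)
    bursts: Tuple[BurstSpec, ...] = ()
    noise_sd: float = 1.0
    noise_alpha: float = 0.0
    seed: int = 0
    channel_labels: Optional[Tuple[str, ...]] = None
    condition: Optional[str] = None
    subject: Optional[str] = None

    def __post_init__(self):
        if self.n_trials < 1 or self.n_channels < 1:
            raise InvalidParameterError("need at least 1 trial and 1 channel")
        lo, hi = self.epoch_window_ms
        if not lo < 0 < hi:
            raise InvalidParameterError(
                f"epoch window must bracket stimulus onset (t=0), got {self.epoch_window_ms}"
            )
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        nyq = self.sampling_rate / 2.0
        for b in self.bursts:
            if b.frequency >= nyq:
                raise InvalidParameterError(
                    f"burst frequency {b.frequency} Hz >= Nyquist ({nyq} Hz)"
                )
        object.__setattr__(self, "bursts", tuple(self.bursts))
        if self.channel_labels is not None:
            labels = tuple(str(c) for c in self.channel_labels)
            if len(labels) != self.n_channels:
                raise InvalidParameterError(
                    f"{len(labels)} labels for {self.n_channels} channels"
                )
            object.__setattr__(self, "channel_labels", labels)

    def labels(self) -> list:
        if self.channel_labels is not None:
            return list(self.channel_labels)
        if self.n_channels <= len(DEFAULT_MONTAGE):
            return list(DEFAULT_MONTAGE[: self.n_channels])
        return [f"Ch{i + 1}" for i in range(self.n_channels)]


def _time_axis(spec: SyntheticSpec) -> np.ndarray:
    dt = 1000.0 / spec.sampling_rate
    n = int(round((spec.epoch_window_ms[1] - spec.epoch_window_ms[0]) / dt)) + 1
    return spec.epoch_window_ms[0] + dt * np.arange(n)


def _shaped_noise(rng: np.random.Generator, shape, sd: float, alpha: float) -> np.ndarray:
    """Gaussian noise with a 1/f^alpha amplitude spectrum, unit-SD normalized."""
    white = rng.standard_normal(shape)
    if sd == 0:
        return np.zeros(shape)
    if alpha == 0:
        return sd * white
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-alpha / 2.0)
    scale[0] = 0.0  # no DC power
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * scale, n=n, axis=-1)
    shaped /= shaped.std(axis=-1, keepdims=True)
    return sd * shaped


def generate(spec: SyntheticSpec) -> EpochedData:
    """Render the dataset described by ``spec``.

    data = sum of bursts + noise, per trial and channel; metadata
    (sampling rate, time axis, labels, condition, subject) populated.
    """
    rng = np.random.default_rng(spec.seed)
    time_ms = _time_axis(spec)
    t_s = time_ms / 1000.0
    labels = spec.labels()
    data = np.zeros((spec.n_trials, spec.n_channels, len(time_ms)))

    for burst in spec.bursts:
        if burst.channels is None:
            ch_idx = list(range(spec.n_channels))
        else:
            missing = [c for c in burst.channels if c not in labels]
            if missing:
                raise InvalidParameterError(
                    f"burst channels {missing} not in montage {labels}"
                )
            ch_idx = [labels.index(c) for c in burst.channels]
        center_s = burst.center_latency_ms / 1000.0
        if burst.envelope == "gaussian":
            sigma_s = burst.duration_ms / 1000.0 / _FWHM_FACTOR
            env = np.exp(-((t_s - center_s) ** 2) / (2.0 * sigma_s**2))
        else:
            half = burst.duration_ms / 2000.0
            env = ((t_s >= center_s - half) & (t_s <= center_s + half)).astype(float)
        # Phases are drawn per trial even when locked, so that switching the
        # policy does not shift the noise stream: determinism per field.
        jitter = rng.uniform(0.0, 2.0 * math.pi, size=spec.n_trials)
        for tr in range(spec.n_trials):
            phase = jitter[tr] if burst.phase_policy == "jittered" else burst.phase
            wave = burst.amplitude * env * np.cos(
                2.0 * math.pi * burst.frequency * t_s + phase
            )
            for c in ch_idx:
                data[tr, c] += wave

    data += _shaped_noise(
        rng, data.shape, spec.noise_sd, spec.noise_alpha
    )
    return EpochedData(
        data=data,
        sampling_rate=spec.sampling_rate,
        time_ms=time_ms,
        channel_labels=labels,
        condition=spec.condition,
        subject=spec.subject,
    )


# ---------------------------------------------------------------------------
# Fixture sets
# ---------------------------------------------------------------------------

#: Conditions of the tutorial-like 2x2 (Modality x Ostension) infant design:
#: direct gaze (DG), averted gaze (AG), infant- and adult-directed speech.
TUTORIAL_CONDITIONS = ("DG", "AG", "IDS", "ADS")
TUTORIAL_SUBJECTS = ("01", "02", "03")
_FRONTAL = ("Fp1", "Fpz", "Fp2")


def _tutorial_bursts(condition: str) -> Tuple[BurstSpec, ...]:
    """Condition-specific oscillatory content for the tutorial-like set.

    The gaze conditions differ in frontal gamma: DG carries a 35 Hz burst
    around 300 ms over frontal channels (AG does not), emulating an induced
    gamma response to ostensive visual stimuli.  The speech conditions carry
    a weaker, later low-beta burst so that every condition has structure.
    """
    if condition == "DG":
        return (
            BurstSpec(35.0, 300.0, 120.0, 3.0, phase_policy="locked", channels=_FRONTAL),
        )
    if condition == "AG":
        return ()
    if condition == "IDS":
        return (
            BurstSpec(15.0, 500.0, 200.0, 1.5, phase_policy="jittered", channels=("T7", "T8")),
        )
    return (
        BurstSpec(15.0, 500.0, 200.0, 0.8, phase_policy="jittered", channels=("T7", "T8")),
    )


def tutorial_spec(condition: str, subject: str, seed: int = 0) -> SyntheticSpec:
    """Spec for one subject x condition cell of the tutorial-like dataset.

    12 trials x 19 channels at 500 Hz, epochs -500..+1500 ms (1001 samples),
    matching a typical infant event-related design; per-cell seed derived
    from the base seed, subject and condition.
    """
    sub_seed = (
        int(seed) * 1009
        + TUTORIAL_SUBJECTS.index(subject) * 101
        + TUTORIAL_CONDITIONS.index(condition)
    ) % (2**31)
    return SyntheticSpec(
        n_trials=12,
        n_channels=19,
        sampling_rate=500.0,
        epoch_window_ms=(-500.0, 1500.0),
        bursts=_tutorial_bursts(condition),
        noise_sd=1.0,
        seed=sub_seed,
        condition=condition,
        subject=subject,
    )


def make_fixture_set(kind: str, out_dir, seed: int = 0, write_set: bool = False):
    """Write a self-contained fixture dataset under ``out_dir``.

    kind='tiny'
        One file: 5 trials x 4 channels at 250 Hz (fast unit-test fodder).
    kind='tutorial'
        3 subjects x 4 conditions (DG/AG/IDS/ADS), 12 trials x 19 channels
        at 500 Hz, epochs -500..+1500 ms, plus a ready-to-run project
        config.  No real data involved.

    Files are HDF5 ``plain_matrix`` containers under ``out_dir/import``;
    with ``write_set=True`` an EEGLAB-style .set copy is written alongside.
    Returns the list of written paths.
    """
    from . import io_project

    out_dir = Path(out_dir)
    imp = out_dir / "import"
    imp.mkdir(parents=True, exist_ok=True)
    written = []
    if kind == "tiny":
        spec = SyntheticSpec(
            n_trials=5,
            n_channels=4,
            sampling_rate=250.0,
            epoch_window_ms=(-200.0, 800.0),
            bursts=(BurstSpec(20.0, 300.0, 150.0, 2.0, channels=None),),
            noise_sd=0.5,
            seed=int(seed) % (2**31),
            condition="tiny",
            subject="01",
        )
        epochs = generate(spec)
        p = imp / "01_tiny.h5"
        io_project.write_plain(epochs, p)
        written.append(p)
        if write_set:
            ps = imp / "01_tiny.set"
            io_project.write_eeglab_set(epochs, ps)
            written.append(ps)
    elif kind == "tutorial":
        for subject in TUTORIAL_SUBJECTS:
            for condition in TUTORIAL_CONDITIONS:
                epochs = generate(tutorial_spec(condition, subject, seed))
                p = imp / f"{subject}_{condition}.h5"
                io_project.write_plain(epochs, p)
                written.append(p)
                if write_set:
                    ps = imp / f"{subject}_{condition}.set"
                    io_project.write_eeglab_set(epochs, ps)
                    written.append(ps)
        cfg = io_project.ProjectConfig(
            root=out_dir,
            subjects=list(TUTORIAL_SUBJECTS),
            conditions=list(TUTORIAL_CONDITIONS),
        )
        cfg_path = out_dir / "project.yaml"
        cfg.save(cfg_path)
        written.append(cfg_path)
    else:
        raise InvalidParameterError(f"kind must be 'tiny' or 'tutorial', got {kind!r}")
    return written
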