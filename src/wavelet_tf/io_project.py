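"""File formats and multi-subject project plumbing.

Supported formats
-----------------
* EEGLAB ``.set`` (read): a MATLAB-v5 file holding the ``EEG`` struct, with
  the data either inline or in a sibling ``.fdt`` float32 file.  Only the
  one-trigger-per-epoch design is supported: every epoch must carry exactly
  one event, at a common latency.
* ``plain_matrix`` (read/write): a documented HDF5 layout for GUI-free
  pipelines and fixtures — datasets ``data`` (trials x channels x samples),
  ``time_ms``, ``channels``, ``fs``, plus ``condition``/``subject`` attrs.
* WT container (read/write): MATLAB-v5 file holding the transformed tensor
  under the variable name ``WT`` (Channel x Frequency x Time) with axis
  variables ``Fa`` (Hz) and ``tim`` (ms) for compatibility with the
  ERPWAVELAB data structure; package provenance is namespaced under
  ``wtf_meta`` to avoid collisions.

:func:`run_project` batches transform -> chop -> baseline over a
subjects x conditions grid, writing one WT file per cell plus a manifest
that makes re-runs idempotent.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import yaml
from scipy.io import loadmat, savemat

from .adjust import BaselineSpec, baseline_correct, chop_edges
from .containers import EpochedData, TFResult
from .errors import (
    InvalidParameterError,
    MalformedFileError,
    UnsupportedDesignError,
)
from .transform import transform_evoked, transform_total_induced
from .wavelets import WaveletSpec, build_bank

# ---------------------------------------------------------------------------
# plain_matrix (HDF5)
# ---------------------------------------------------------------------------


def write_plain(epochs: EpochedData, path) -> Path:
    """Write the documented HDF5 layout (data, time_ms, channels, fs)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("time_ms", data=epochs.time_ms)
        f.create_dataset(
            "channels",
            data=np.array(epochs.channel_labels, dtype=h5py.string_dtype()),
        )
        f.create_dataset("fs", data=float(epochs.sampling_rate))
        if epochs.condition is not None:
            f.attrs["condition"] = epochs.condition
        if epochs.subject is not None:
            f.attrs["subject"] = epochs.subject
    return path


def _read_plain(path: Path) -> EpochedData:
    with h5py.File(path, "r") as f:
        for key in ("data", "time_ms", "channels", "fs"):
            if key not in f:
                raise MalformedFileError(f"{path}: missing dataset {key!r}")
        data = f["data"][()]
        time_ms = f["time_ms"][()]
        channels = [
            c.decode() if isinstance(c, bytes) else str(c) for c in f["channels"][()]
        ]
        fs = float(f["fs"][()])
        condition = f.attrs.get("condition")
        subject = f.attrs.get("subject")
    return EpochedData(
        data=data,
        sampling_rate=fs,
        time_ms=time_ms,
        channel_labels=channels,
        condition=None if condition is None else str(condition),
        subject=None if subject is None else str(subject),
    )


# ---------------------------------------------------------------------------
# EEGLAB .set / .fdt
# ---------------------------------------------------------------------------


def _mat_scalar(value):
    arr = np.asarray(value).ravel()
    return arr[0] if arr.size else None


def _read_eeglab(path: Path) -> EpochedData:
    mat = loadmat(path, squeeze_me=False, struct_as_record=False)
    if "EEG" in mat:
        eeg = mat["EEG"].ravel()[0]
    else:
        # pop_saveset may store struct fields as top-level variables
        class _NS:  # noqa: D401 - ad-hoc namespace
            pass

        eeg = _NS()
        for k, v in mat.items():
            if not k.startswith("__"):
                setattr(eeg, k, v)
    srate = _mat_scalar(getattr(eeg, "srate", None))
    if srate is None or not np.isfinite(float(srate)) or float(srate) <= 0:
        raise MalformedFileError(f"{path}: missing or invalid sampling rate (srate)")
    srate = float(srate)
    nbchan = int(_mat_scalar(getattr(eeg, "nbchan", 0)) or 0)
    pnts = int(_mat_scalar(getattr(eeg, "pnts", 0)) or 0)
    trials = int(_mat_scalar(getattr(eeg, "trials", 1)) or 1)

    data = getattr(eeg, "data", None)
    if data is None:
        raise MalformedFileError(f"{path}: no data field")
    if isinstance(data, np.ndarray) and data.dtype.kind in ("U", "S"):
        # data stored in a sibling .fdt file: float32, column-major,
        # shape (nbchan, pnts * trials)
        fdt_name = str(np.asarray(data).ravel()[0])
        fdt = path.parent / Path(fdt_name).name
        if not fdt.exists():
            fdt = path.with_suffix(".fdt")
        if not fdt.exists():
            raise MalformedFileError(f"{path}: referenced data file {fdt_name} not found")
        raw = np.fromfile(fdt, dtype="<f4")
        if raw.size != nbchan * pnts * trials:
            raise MalformedFileError(
                f"{fdt}: expected {nbchan * pnts * trials} float32 values, got {raw.size}"
            )
        data = raw.reshape((nbchan, pnts, trials), order="F")
    else:
        data = np.asarray(data, dtype=np.float64)
        if data.ndim == 2:
            data = data.reshape((nbchan, pnts, max(trials, 1)), order="F")
    # (nbchan, pnts, trials) -> (trials, channels, samples)
    data = np.transpose(data, (2, 0, 1)).astype(np.float64)

    # one single trigger per segment/epoch
    events = getattr(eeg, "event", None)
    if events is not None and np.asarray(events).size:
        ev = np.asarray(events).ravel()
        epochs_of_events = []
        for e in ev:
            ep = _mat_scalar(getattr(e, "epoch", 1))
            epochs_of_events.append(int(ep) if ep is not None else 1)
        counts = np.bincount(np.asarray(epochs_of_events) - 1, minlength=trials)
        if np.any(counts > 1):
            bad = int(np.argmax(counts > 1)) + 1
            raise UnsupportedDesignError(
                f"{path}: epoch {bad} contains {int(counts[bad - 1])} events; "
                "only one trigger per epoch is supported"
            )

    xmin = _mat_scalar(getattr(eeg, "xmin", None))
    if xmin is None:
        raise MalformedFileError(f"{path}: missing epoch start time (xmin)")
    time_ms = (float(xmin) + np.arange(pnts) / srate) * 1000.0

    chanlocs = getattr(eeg, "chanlocs", None)
    labels = []
    if chanlocs is not None and np.asarray(chanlocs).size:
        for cl in np.asarray(chanlocs).ravel():
            lab = getattr(cl, "labels", None)
            lab = None if lab is None else _mat_scalar(lab)
            labels.append(str(lab) if lab is not None else f"Ch{len(labels) + 1}")
    if len(labels) != nbchan:
        labels = [f"Ch{i + 1}" for i in range(nbchan)]

    return EpochedData(
        data=data,
        sampling_rate=srate,
        time_ms=time_ms,
        channel_labels=labels,
    )


def write_eeglab_set(epochs: EpochedData, path) -> Path:
    """Write epochs as a minimal EEGLAB-style ``.set`` (MATLAB-v5) file.

    Intended for fixtures and interchange tests; stores the data inline as
    float32 with one event per epoch at stimulus onset.
    """
    path = Path(path)
    n_tr, n_ch, n_s = epochs.data.shape
    data = np.transpose(epochs.data, (1, 2, 0)).astype(np.float32)
    onset_idx = int(np.argmin(np.abs(epochs.time_ms))) + 1  # 1-based
    event = np.zeros((1, n_tr), dtype=[("type", "O"), ("latency", "O"), ("epoch", "O")])
    for i in range(n_tr):
        event[0, i] = ("stim", float(onset_idx + i * n_s), float(i + 1))
    chanlocs = np.zeros((1, n_ch), dtype=[("labels", "O")])
    for i, lab in enumerate(epochs.channel_labels):
        chanlocs[0, i] = (lab,)
    eeg = {
        "setname": epochs.condition or "epochs",
        "data": data,
        "srate": float(epochs.sampling_rate),
        "nbchan": float(n_ch),
        "pnts": float(n_s),
        "trials": float(n_tr),
        "xmin": float(epochs.time_ms[0]) / 1000.0,
        "xmax": float(epochs.time_ms[-1]) / 1000.0,
        "times": epochs.time_ms.astype(np.float64),
        "chanlocs": chanlocs,
        "event": event,
        "epoch": np.zeros((0, 0)),
        "icawinv": np.zeros((0, 0)),
        "icaweights": np.zeros((0, 0)),
        "icasphere": np.zeros((0, 0)),
        "ref": "common",
    }
    savemat(path, {"EEG": eeg}, format="5")
    return path


def read_epochs(path, format: str = None) -> EpochedData:
    """Read epoched EEG from ``.set``/``.fdt`` or a plain_matrix HDF5 file.

    ``format`` is 'eeglab_set' or 'plain_matrix'; inferred from the file
    extension when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise MalformedFileError(f"no such file: {path}")
    if format is None:
        format = "eeglab_set" if path.suffix.lower() == ".set" else "plain_matrix"
    if format == "eeglab_set":
        return _read_eeglab(path)
    if format == "plain_matrix":
        return _read_plain(path)
    raise InvalidParameterError(
        f"format must be 'eeglab_set' or 'plain_matrix', got {format!r}"
    )


# ---------------------------------------------------------------------------
# WT container (MATLAB-v5)
# ---------------------------------------------------------------------------


def write_wt(result: TFResult, path) -> Path:
    """Persist a TFResult as a MATLAB-v5 container.

    The tensor is stored under ``WT`` (Channel x Frequency x Time) with
    axes ``Fa`` (frequencies, Hz) and ``tim`` (time, ms) following the
    ERPWAVELAB structure; measure, labels and provenance go into the
    namespaced ``wtf_meta`` JSON string.
    """
    path = Path(path)
    meta = {
        "measure": result.measure,
        "channel_labels": result.channel_labels,
        "n_trials_averaged": int(result.n_trials_averaged),
        "chopped_ms": float(result.chopped_ms),
        "condition": result.condition,
        "subject": result.subject,
        "baseline": None
        if result.baseline is None
        else {"mode": result.baseline.mode, "window": result.baseline.window},
    }
    payload = {
        "WT": result.values,
        "Fa": result.frequencies.reshape(1, -1),
        "tim": result.time_ms.reshape(1, -1),
        "wtf_meta": json.dumps(meta),
    }
    if result.sem is not None:
        payload["wtf_sem"] = result.sem
    savemat(path, payload, format="5")
    return path


def read_wt(path) -> TFResult:
    """Inverse of :func:`write_wt`."""
    path = Path(path)
    if not path.exists():
        raise MalformedFileError(f"no such file: {path}")
    mat = loadmat(path, squeeze_me=False)
    if "WT" not in mat:
        raise MalformedFileError(f"{path}: missing WT variable")
    values = mat["WT"]
    if "Fa" not in mat or "tim" not in mat:
        raise MalformedFileError(f"{path}: missing Fa/tim axis variables")
    freqs = np.asarray(mat["Fa"]).ravel()
    tim = np.asarray(mat["tim"]).ravel()
    meta = {}
    if "wtf_meta" in mat:
        meta = json.loads(str(np.asarray(mat["wtf_meta"]).ravel()[0]))
    baseline = None
    if meta.get("baseline"):
        baseline = BaselineSpec(
            mode=meta["baseline"]["mode"],
            window=None
            if meta["baseline"]["window"] is None
            else tuple(meta["baseline"]["window"]),
        )
    measure = meta.get("measure", "complex" if np.iscomplexobj(values) else "amplitude")
    return TFResult(
        values=values,
        measure=measure,
        frequencies=freqs,
        time_ms=tim,
        channel_labels=meta.get(
            "channel_labels", [f"Ch{i + 1}" for i in range(values.shape[0])]
        ),
        n_trials_averaged=int(meta.get("n_trials_averaged", 1)),
        baseline=baseline,
        chopped_ms=float(meta.get("chopped_ms", 0.0)),
        condition=meta.get("condition"),
        subject=meta.get("subject"),
        sem=mat.get("wtf_sem"),
    )


# ---------------------------------------------------------------------------
# Project configuration and batch runs
# ---------------------------------------------------------------------------


@dataclass
class AnalysisParams:
    """Default analysis pipeline parameters.

    Frequencies 10-90 Hz in 1 Hz steps, 7-cycle normalized wavelets,
    total-induced amplitude, 300 ms chopped per edge, subtractive baseline
    over the full remaining pre-stimulus window.
    """

    fmin: float = 10.0
    fmax: float = 90.0
    fstep: float = 1.0
    cycles: float = 7.0
    normalization: str = "amplitude"
    measure: str = "amplitude"
    mode: str = "induced"  # 'induced' or 'evoked'
    chop_ms: float = 300.0
    baseline_mode: str = "subtractive"
    baseline_window: Optional[Sequence[float]] = None
    compute_sem: bool = True

    def validate(self, sampling_rate: float):
        # building the spec raises InvalidParameterError on bad parameters
        WaveletSpec.from_range(
            self.fmin, self.fmax, self.fstep, self.cycles, sampling_rate,
            self.normalization,
        )
        if self.mode not in ("induced", "evoked"):
            raise InvalidParameterError(f"mode must be induced|evoked, got {self.mode!r}")
        if self.measure not in ("amplitude", "power", "complex"):
            raise InvalidParameterError(f"bad measure {self.measure!r}")
        BaselineSpec(
            self.baseline_mode,
            None if self.baseline_window is None else tuple(self.baseline_window),
        )


@dataclass
class ProjectConfig:
    """Multi-subject, multi-condition project layout.

    Inputs live in ``<root>/import/<subject>_<condition>.(h5|set)``;
    outputs in ``<root>/wt/``; exported statistics tables default to
    ``<root>/Statistics/``.
    """

    root: Path
    subjects: list
    conditions: list
    params: AnalysisParams = field(default_factory=AnalysisParams)

    def __post_init__(self):
        self.root = Path(self.root)
        self.subjects = [str(s) for s in self.subjects]
        self.conditions = [str(c) for c in self.conditions]
        if len(set(self.subjects)) != len(self.subjects):
            raise InvalidParameterError("subject labels must be unique")
        if len(set(self.conditions)) != len(self.conditions):
            raise InvalidParameterError("condition labels must be unique")
        if not self.subjects or not self.conditions:
            raise InvalidParameterError("need at least one subject and one condition")
        if isinstance(self.params, dict):
            self.params = AnalysisParams(**self.params)

    @property
    def import_dir(self) -> Path:
        return self.root / "import"

    @property
    def wt_dir(self) -> Path:
        return self.root / "wt"

    @property
    def statistics_dir(self) -> Path:
        return self.root / "Statistics"

    def input_path(self, subject: str, condition: str) -> Optional[Path]:
        for ext in (".h5", ".set"):
            p = self.import_dir / f"{subject}_{condition}{ext}"
            if p.exists():
                return p
        return None

    def output_path(self, subject: str, condition: str) -> Path:
        return self.wt_dir / f"{subject}_{condition}.wt.mat"

    def save(self, path) -> Path:
        path = Path(path)
        doc = {
            "root": str(self.root),
            "subjects": self.subjects,
            "conditions": self.conditions,
            "params": asdict(self.params),
        }
        with open(path, "w") as f:
            if path.suffix in (".yaml", ".yml"):
                yaml.safe_dump(doc, f, sort_keys=False)
            else:
                json.dump(doc, f, indent=2)
        return path

    @classmethod
    def load(cls, path) -> "ProjectConfig":
        path = Path(path)
        if not path.exists():
            raise MalformedFileError(f"no such config file: {path}")
        with open(path) as f:
            doc = yaml.safe_load(f)
        try:
            params = AnalysisParams(**doc.get("params", {}))
            return cls(
                root=doc["root"],
                subjects=doc["subjects"],
                conditions=doc["conditions"],
                params=params,
            )
        except (KeyError, TypeError) as exc:
            raise MalformedFileError(f"{path}: invalid project config ({exc})") from exc


@dataclass
class RunReport:
    """Outcome of :func:`run_project`: per-cell status plus failure details."""

    computed: list = field(default_factory=list)
    skipped: list = field(default_factory=list)
    failures: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def _params_key(params: AnalysisParams) -> str:
    return json.dumps(asdict(params), sort_keys=True, default=str)


def analyze_epochs(epochs: EpochedData, params: AnalysisParams) -> TFResult:
    """Run the configured pipeline (transform -> chop -> baseline) on one dataset."""
    params.validate(epochs.sampling_rate)
    bank = build_bank(
        WaveletSpec.from_range(
            params.fmin, params.fmax, params.fstep, params.cycles,
            epochs.sampling_rate, params.normalization,
        )
    )
    if params.mode == "induced":
        result = transform_total_induced(
            epochs, bank, measure=params.measure,
            compute_sem=params.compute_sem and params.measure != "complex",
        )
    else:
        result = transform_evoked(epochs, bank, measure=params.measure)
    if params.chop_ms:
        result = chop_edges(result, params.chop_ms)
    if params.baseline_mode != "none" and params.measure != "complex":
        result = baseline_correct(
            result,
            BaselineSpec(
                params.baseline_mode,
                None if params.baseline_window is None else tuple(params.baseline_window),
            ),
        )
    return result


def run_project(config: ProjectConfig, force: bool = False) -> RunReport:
    """Transform every subject x condition input into a WT file.

    Idempotent: a cell is skipped when its output exists and the manifest
    records the same input file (mtime + size) and parameters, unless
    ``force``.  A missing or unreadable input is recorded as a per-cell
    failure; the run continues.
    """
    report = RunReport()
    config.wt_dir.mkdir(parents=True, exist_ok=True)
    config.statistics_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = config.wt_dir / "manifest.json"
    manifest = {}
    if manifest_path.exists():
        with open(manifest_path) as f:
            manifest = json.load(f)
    pkey = _params_key(config.params)
    for subject in config.subjects:
        for condition in config.conditions:
            cell = f"{subject}_{condition}"
            in_path = config.input_path(subject, condition)
            if in_path is None:
                report.failures[cell] = (
                    f"missing input {config.import_dir / (cell + '.h5')} (or .set)"
                )
                continue
            stat = in_path.stat()
            entry = {
                "input": str(in_path),
                "input_mtime": stat.st_mtime,
                "input_size": stat.st_size,
                "params": pkey,
            }
            out_path = config.output_path(subject, condition)
            prev = manifest.get(cell)
            if (
                not force
                and out_path.exists()
                and prev is not None
                and {k: prev.get(k) for k in entry} == entry
            ):
                report.skipped.append(cell)
                continue
            try:
                epochs = read_epochs(in_path)
                epochs.subject, epochs.condition = subject, condition
                result = analyze_epochs(epochs, config.params)
                write_wt(result, out_path)
            except Exception as exc:  # per-cell isolation by contract
                report.failures[cell] = f"{type(exc).__name__}: {exc}"
                continue
            entry["output"] = str(out_path)
            entry["written_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
            manifest[cell] = entry
            report.computed.append(cell)
    with open(manifest_path, "w") as f:
        json.dump(manifest, f, indent=2)
    return report
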