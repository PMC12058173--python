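"""Window averaging and export of statistics tables.

The exported quantity is a double average: the unweighted mean of a
TFResult over all grid points inside a time window and a frequency window
(endpoints snapped to the nearest sample/frequency and inclusive), per
channel.  Tables are tab-separated text with one row per subject and one
column per condition x channel (condition-major), ready for third-party
statistical packages; no inference is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np

from .adjust import average_channels, snap_window
from .containers import TFResult, check_compatible
from .errors import IncompatibleResultsError, InvalidParameterError

#: A channel selector: a single label, or a group of labels to average.
ChannelSel = Union[str, Sequence[str]]


@dataclass(frozen=True)
class StatWindow:
    """Selection for a statistics export.

    ``channels`` entries may be single labels or label groups (sequences),
    the latter exported as the unweighted average over the group.
    """

    time_window: Tuple[float, float]
    freq_window: Tuple[float, float]
    subjects: Tuple[str, ...]
    conditions: Tuple[str, ...]
    channels: Tuple[ChannelSel, ...]

    def __post_init__(self):
        if not self.subjects:
            raise InvalidParameterError("subject selection must not be empty")
        if not self.conditions:
            raise InvalidParameterError("condition selection must not be empty")
        if not self.channels:
            raise InvalidParameterError("channel selection must not be empty")
        object.__setattr__(self, "subjects", tuple(str(s) for s in self.subjects))
        object.__setattr__(self, "conditions", tuple(str(c) for c in self.conditions))
        chans = tuple(
            c if isinstance(c, str) else tuple(str(x) for x in c) for c in self.channels
        )
        object.__setattr__(self, "channels", chans)


def window_mean(
    result: TFResult,
    time_window: Sequence[float],
    freq_window: Sequence[float],
    channel: ChannelSel,
) -> float:
    """Mean over all (frequency, time) grid points inside the windows.

    Windows snap to the nearest grid point and are inclusive of both snapped
    endpoints; single-point windows select exactly one grid point.
    """
    if result.measure == "complex":
        raise InvalidParameterError(
            "window means are defined for real-valued measures; take the "
            "modulus (amplitude) first"
        )
    if not isinstance(channel, str):
        result = average_channels(result, list(channel))
        channel = result.channel_labels[0]
    ci = result.channel_index(channel)
    t0, t1 = snap_window(result.time_ms, time_window, name="time window")
    f0, f1 = snap_window(result.frequencies, freq_window, name="frequency window")
    block = result.values[ci, f0 : f1 + 1, t0 : t1 + 1]
    return float(np.mean(block))


def _column_name(condition: str, channel: ChannelSel) -> str:
    label = channel if isinstance(channel, str) else "+".join(channel)
    return f"{condition}_{label}"


def export_table(
    results: Dict[Tuple[str, str], TFResult],
    window: StatWindow,
    path,
) -> Path:
    """Write the subjects x (condition x channel) window-mean table.

    ``results`` maps (subject, condition) to a TFResult; every selected cell
    must be present and all results must share axes.  The first column is
    the subject label; remaining columns are ordered condition-major then
    channel, with header names ``condition_channel``.  Values carry full
    double precision ('%.17g') so they parse back exactly.
    """
    missing = [
        (s, c)
        for s in window.subjects
        for c in window.conditions
        if (s, c) not in results
    ]
    if missing:
        raise InvalidParameterError(f"missing subject x condition results: {missing}")
    selected = [results[(s, c)] for s in window.subjects for c in window.conditions]
    ref = selected[0]
    for r in selected[1:]:
        try:
            check_compatible(ref, r, context="export_table")
        except IncompatibleResultsError as exc:
            raise IncompatibleResultsError(
                f"{exc} (subject {r.subject!r}, condition {r.condition!r})"
            ) from exc

    header = ["subject"] + [
        _column_name(c, ch) for c in window.conditions for ch in window.channels
    ]
    lines = ["\t".join(header)]
    for s in window.subjects:
        row = [s]
        for c in window.conditions:
            res = results[(s, c)]
            for ch in window.channels:
                v = window_mean(res, window.time_window, window.freq_window, ch)
                row.append(f"{v:.17g}")
        lines.append("\t".join(row))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_table(path) -> "pandas.DataFrame":  # noqa: F821 - import deferred
    """Parse an exported .tab file back into a DataFrame indexed by subject."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", index_col="subject", dtype={"subject": str})
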