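"""Plotting: time-frequency rasters, condition differences, 2D scalp maps.

Scalp maps project electrode positions onto the unit disc (vertex at the
origin, nose up) and interpolate a per-channel scalar with a thin-plate
(biharmonic) spline, masked outside the electrode convex hull plus a small
margin.  The per-channel scalar is computed with
:func:`wavelet_tf.stats_export.window_mean`, so a plotted map is exactly
reproducible from the numeric exports — rendering adds no numeric
transformation beyond interpolation and color mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.spatial import ConvexHull, Delaunay

from .containers import TFResult, check_compatible
from .errors import InvalidParameterError, MalformedFileError
from .stats_export import window_mean


@dataclass
class ElectrodeLayout:
    """2D head-plane electrode positions on the unit disc (nose along +y)."""

    labels: list
    xy: np.ndarray

    def __post_init__(self):
        self.labels = [str(l) for l in self.labels]
        self.xy = np.asarray(self.xy, dtype=np.float64)
        if self.xy.shape != (len(self.labels), 2):
            raise InvalidParameterError(
                f"xy must be (n_channels, 2); got {self.xy.shape} for "
                f"{len(self.labels)} labels"
            )
        r = np.hypot(self.xy[:, 0], self.xy[:, 1])
        if np.any(r > 1.0 + 1e-9):
            raise InvalidParameterError(
                "electrode coordinates must lie within the unit disc; "
                "use the from_* readers, which normalize"
            )

    def positions_for(self, channels: Sequence[str]) -> np.ndarray:
        missing = [c for c in channels if c not in self.labels]
        if missing:
            raise InvalidParameterError(
                f"channel(s) {missing} missing from the electrode layout"
            )
        idx = [self.labels.index(c) for c in channels]
        return self.xy[idx]

    @classmethod
    def from_ced(cls, path) -> "ElectrodeLayout":
        """Read an EEGLAB .ced channel-location table (theta/radius columns)."""
        import pandas as pd

        path = Path(path)
        if not path.exists():
            raise MalformedFileError(f"no such layout file: {path}")
        df = pd.read_csv(path, sep=r"\s+")
        cols = {c.lower(): c for c in df.columns}
        if "labels" not in cols or "theta" not in cols or "radius" not in cols:
            raise MalformedFileError(
                f"{path}: .ced file needs 'labels', 'theta', 'radius' columns"
            )
        labels = [str(x) for x in df[cols["labels"]]]
        theta = np.deg2rad(df[cols["theta"]].to_numpy(float))
        radius = df[cols["radius"]].to_numpy(float)
        # EEGLAB polar convention: theta=0 at the nose, clockwise positive;
        # radius 0.5 at the head circumference.
        x = radius * np.sin(theta)
        y = radius * np.cos(theta)
        xy = np.c_[x, y]
        return cls(labels, _fit_unit_disc(xy))

    @classmethod
    def from_sfp(cls, path) -> "ElectrodeLayout":
        """Read a .sfp/.elp cartesian file (label x y z), azimuthally projected."""
        path = Path(path)
        if not path.exists():
            raise MalformedFileError(f"no such layout file: {path}")
        labels, pts = [], []
        for line in path.read_text().splitlines():
            parts = line.split()
            if len(parts) < 4 or parts[0].startswith(("#", "//")):
                continue
            labels.append(parts[0])
            pts.append([float(v) for v in parts[1:4]])
        if not labels:
            raise MalformedFileError(f"{path}: no electrode rows found")
        pts = np.asarray(pts)
        # azimuthal equidistant projection: angle from vertex -> radius
        r3 = np.linalg.norm(pts, axis=1)
        r3[r3 == 0] = 1.0
        unit = pts / r3[:, None]
        polar = np.arccos(np.clip(unit[:, 2], -1.0, 1.0))
        azim = np.arctan2(unit[:, 1], unit[:, 0])
        rad = polar / math.pi * 2.0 * 0.5
        xy = np.c_[rad * np.cos(azim), rad * np.sin(azim)]
        return cls(labels, _fit_unit_disc(xy))

    @classmethod
    def read(cls, path) -> "ElectrodeLayout":
        path = Path(path)
        if path.suffix.lower() == ".ced":
            return cls.from_ced(path)
        return cls.from_sfp(path)


def _fit_unit_disc(xy: np.ndarray) -> np.ndarray:
    rmax = np.hypot(xy[:, 0], xy[:, 1]).max()
    if rmax > 1.0:
        xy = xy / rmax
    return xy


def diff_conditions(a: TFResult, b: TFResult) -> TFResult:
    """Elementwise condition difference a - b with provenance 'A - B'."""
    if a.measure == "complex":
        raise InvalidParameterError("condition differences require a real measure")
    check_compatible(a, b, context="diff_conditions")
    sem = None
    if a.sem is not None and b.sem is not None:
        sem = np.sqrt(a.sem**2 + b.sem**2)
    cond = f"{a.condition or 'A'} - {b.condition or 'B'}"
    return a.copy_with(values=a.values - b.values, condition=cond, sem=sem)


def _select_channel(result: TFResult, channel) -> Tuple[np.ndarray, str, Optional[np.ndarray]]:
    from .adjust import average_channels

    if channel is None and result.n_channels == 1:
        channel = result.channel_labels[0]
    if isinstance(channel, str):
        ci = result.channel_index(channel)
        return result.values[ci], channel, None if result.sem is None else result.sem[ci]
    avg = average_channels(result, list(channel))
    return avg.values[0], avg.channel_labels[0], None if avg.sem is None else avg.sem[0]


def plot_tf(
    result: TFResult,
    channel=None,
    out=None,
    time_range: Optional[Sequence[float]] = None,
    freq_range: Optional[Sequence[float]] = None,
    scale: Optional[Sequence[float]] = None,
    show_sem: bool = False,
    cmap: Optional[str] = None,
    title: Optional[str] = None,
):
    """Render a (time, frequency) raster for one channel or channel average.

    ``channel`` is a label or a sequence of labels (averaged).  ``scale``
    fixes the color limits (min, max).  With ``show_sem`` and an available
    across-trial SEM, a contour is drawn where |value| exceeds its SEM,
    outlining regions whose deviation from baseline exceeds one standard
    error — a descriptive, not inferential, display.

    Returns the output path if ``out`` is given, else the matplotlib figure.
    """
    from .adjust import snap_window

    if result.measure == "complex":
        raise InvalidParameterError("plot the amplitude or power, not complex values")
    if scale is not None and scale[0] >= scale[1]:
        raise InvalidParameterError(f"scale min must be < max, got {scale}")
    values, label, sem = _select_channel(result, channel)
    t0, t1 = (0, len(result.time_ms) - 1)
    f0, f1 = (0, len(result.frequencies) - 1)
    if time_range is not None:
        t0, t1 = snap_window(result.time_ms, time_range, name="time range")
    if freq_range is not None:
        f0, f1 = snap_window(result.frequencies, freq_range, name="frequency range")
    block = values[f0 : f1 + 1, t0 : t1 + 1]
    tt = result.time_ms[t0 : t1 + 1]
    ff = result.frequencies[f0 : f1 + 1]

    diverging = result.baseline is not None or np.any(block < 0)
    if cmap is None:
        cmap = "RdBu_r" if diverging else "viridis"
    vmin, vmax = (scale if scale is not None else (None, None))
    if scale is None and diverging:
        m = np.max(np.abs(block)) or 1.0
        vmin, vmax = -m, m

    fig, ax = plt.subplots(figsize=(7, 4.2))
    mesh = ax.pcolormesh(tt, ff, block, cmap=cmap, vmin=vmin, vmax=vmax, shading="nearest")
    if show_sem and sem is not None:
        semb = sem[f0 : f1 + 1, t0 : t1 + 1]
        with np.errstate(invalid="ignore"):
            ratio = np.abs(block) / np.where(semb > 0, semb, np.inf)
        ax.contour(tt, ff, ratio, levels=[1.0], colors="k", linewidths=0.7)
    ax.axvline(0.0, color="k", lw=0.6, ls="--")
    ax.set_xlabel("Time (ms)")
    ax.set_ylabel("Frequency (Hz)")
    unit = {"amplitude": "µV", "power": "µV²", "dB": "dB"}[result.measure]
    fig.colorbar(mesh, ax=ax, label=f"{result.measure} ({unit})")
    ax.set_title(title or f"{result.condition or ''} {label}".strip())
    fig.tight_layout()
    if out is None:
        return fig
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def _channel_scalars(
    result: TFResult,
    time_sel,
    freq_sel,
) -> np.ndarray:
    """Per-channel scalar for a scalp map via the window_mean reduction."""
    tw = (time_sel, time_sel) if np.isscalar(time_sel) else tuple(time_sel)
    fw = (freq_sel, freq_sel) if np.isscalar(freq_sel) else tuple(freq_sel)
    return np.array(
        [window_mean(result, tw, fw, ch) for ch in result.channel_labels]
    )


def _draw_head(ax):
    head = plt.Circle((0, 0), 1.0, fill=False, color="k", lw=1.2)
    ax.add_patch(head)
    ax.plot([-0.08, 0, 0.08], [0.995, 1.08, 0.995], color="k", lw=1.2)  # nose
    for sx in (-1, 1):
        ear_t = np.linspace(-0.35, 0.35, 20)
        ax.plot(sx * (1.0 + 0.04 * np.cos(ear_t * math.pi)), ear_t * 0.35, color="k", lw=1.0)
    ax.set_xlim(-1.25, 1.25)
    ax.set_ylim(-1.25, 1.25)
    ax.set_aspect("equal")
    ax.axis("off")


def _topo_panel(ax, xy: np.ndarray, vals: np.ndarray, vlim, cmap: str):
    grid = np.linspace(-1.05, 1.05, 101)
    gx, gy = np.meshgrid(grid, grid)
    pts = np.c_[gx.ravel(), gy.ravel()]
    if len(xy) >= 3:
        # thin-plate (biharmonic) spline; mask beyond hull + margin
        interp = RBFInterpolator(xy, vals, kernel="thin_plate_spline")
        z = interp(pts)
        hull = ConvexHull(xy)
        tri = Delaunay(xy[hull.vertices])
        margin = 0.12
        center = xy.mean(axis=0)
        expanded = center + (xy[hull.vertices] - center) * (1.0 + margin)
        tri = Delaunay(expanded)
        inside = tri.find_simplex(pts) >= 0
        z = np.where(inside, z, np.nan)
    else:
        z = np.full(pts.shape[0], float(np.mean(vals)))
        inside = np.hypot(pts[:, 0], pts[:, 1]) <= 1.0
        z = np.where(inside, z, np.nan)
    z = z.reshape(gx.shape)
    mesh = ax.pcolormesh(gx, gy, z, cmap=cmap, vmin=vlim[0], vmax=vlim[1], shading="nearest")
    ax.scatter(xy[:, 0], xy[:, 1], s=6, c="k", zorder=3)
    _draw_head(ax)
    return mesh


def plot_topo2d(
    result: TFResult,
    layout: ElectrodeLayout,
    time=None,
    freq=None,
    series: Optional[Sequence[float]] = None,
    series_axis: str = "time",
    out=None,
    scale: Optional[Sequence[float]] = None,
    cmap: Optional[str] = None,
):
    """2D scalp map(s) of a time/frequency reduction of ``result``.

    Selections (either may be a scalar grid point or a [lo, hi] window):

    * ``time=t, freq=f`` — one timepoint at one frequency;
    * ``time=(t0, t1), freq=f`` — timepoint average at one frequency;
    * ``time=t, freq=(f0, f1)`` — frequency-range average at one timepoint.

    ``series`` plots one panel per listed value of ``series_axis``
    ('time' or 'frequency'), holding the other selection fixed — a time
    topography over frequency or vice versa.

    Returns the written path (``out`` given) or the figure.
    """
    if result.measure == "complex":
        raise InvalidParameterError("scalp maps require a real measure")
    if scale is not None and scale[0] >= scale[1]:
        raise InvalidParameterError(f"scale min must be < max, got {scale}")
    xy = layout.positions_for(result.channel_labels)

    if series is not None:
        panels = [
            (v, freq) if series_axis == "time" else (time, v) for v in series
        ]
    else:
        if time is None or freq is None:
            raise InvalidParameterError("provide both a time and a frequency selection")
        panels = [(time, freq)]

    scalars = [
        _channel_scalars(result, t_sel, f_sel) for (t_sel, f_sel) in panels
    ]
    allv = np.concatenate(scalars)
    diverging = result.baseline is not None or np.any(allv < 0)
    if scale is None:
        m = np.max(np.abs(allv)) or 1.0
        vlim = (-m, m) if diverging else (float(allv.min()), float(allv.max() or 1.0))
        if vlim[0] == vlim[1]:
            vlim = (vlim[0] - 0.5, vlim[1] + 0.5)
    else:
        vlim = tuple(scale)
    if cmap is None:
        cmap = "RdBu_r" if diverging else "viridis"

    n = len(panels)
    fig, axes = plt.subplots(1, n, figsize=(3.0 * n, 3.4), squeeze=False)
    for ax, vals, (t_sel, f_sel) in zip(axes[0], scalars, panels):
        mesh = _topo_panel(ax, xy, vals, vlim, cmap)
        t_lab = t_sel if np.isscalar(t_sel) else f"{t_sel[0]}-{t_sel[1]}"
        f_lab = f_sel if np.isscalar(f_sel) else f"{f_sel[0]}-{f_sel[1]}"
        ax.set_title(f"{t_lab} ms, {f_lab} Hz", fontsize=9)
    fig.colorbar(mesh, ax=axes[0].tolist(), shrink=0.8)
    if out is None:
        return fig
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
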