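"""Multirate recording I/O, per-channel min-max scaling and resampling.

A :class:`RecordingStream` holds one subject's raw multichannel signal.  Each
channel keeps its own timestamp vector (seconds since recording start) so
channels sampled at different rates coexist without resampling.

Two CSV dialects are supported:

* wide  — ``datetime,X,Y,Z,EDA,HR,TEMP,label,id``; channels sampled at
  different rates are outer-joined on the timestamp column, absent cells are
  left blank and dropped again on read, so the round trip is lossless.
* long  — ``id,datetime,channel,value,label``; one row per sample.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChannelRegistry",
    "RecordingStream",
    "MinMaxScaler",
    "read_wide_csv",
    "write_wide_csv",
    "read_long_csv",
    "write_long_csv",
    "minmax_scale",
    "resample_channel",
]

#: Default gap threshold (seconds) separating monitoring sessions.
DEFAULT_GAP_S = 900.0


@dataclass(frozen=True)
class ChannelRegistry:
    """Canonical channel names and their nominal sampling rates (Hz).

    The rate actually stored on a stream is the one measured from the file;
    the registry values are only used when synthesising data or when a file
    contains a single sample (no measurable rate).
    """

    expected_rates: dict[str, float] = field(
        default_factory=lambda: {
            "ACC_X": 32.0,
            "ACC_Y": 32.0,
            "ACC_Z": 32.0,
            "EDA": 4.0,
            "HR": 1.0,
            "TEMP": 4.0,
        }
    )

    #: column aliases accepted in wide CSV headers
    aliases: dict[str, str] = field(
        default_factory=lambda: {
            "X": "ACC_X",
            "Y": "ACC_Y",
            "Z": "ACC_Z",
            "ACC_X": "ACC_X",
            "ACC_Y": "ACC_Y",
            "ACC_Z": "ACC_Z",
            "EDA": "EDA",
            "HR": "HR",
            "TEMP": "TEMP",
            "ST": "TEMP",
        }
    )

    @property
    def names(self) -> list[str]:
        return list(self.expected_rates)

    def canonical(self, column: str) -> str | None:
        return self.aliases.get(column.strip())


@dataclass
class RecordingStream:
    """One subject's multichannel, multirate signal.

    Parameters
    ----------
    subject:
        Subject identifier.
    channels:
        Map channel name -> ``(timestamps, values)``; timestamps are seconds
        since recording start and strictly increasing per channel.
    rates:
        Map channel name -> sampling rate in Hz.
    labels:
        Optional map channel name -> integer stress level per sample
        (0=Low, 1=Medium, 2=High).
    """

    subject: str
    channels: dict[str, tuple[np.ndarray, np.ndarray]]
    rates: dict[str, float]
    labels: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for name, (t, v) in self.channels.items():
            t = np.asarray(t, dtype=float)
            v = np.asarray(v, dtype=float)
            if t.shape != v.shape:
                raise ValueError(f"channel {name}: {len(t)} timestamps vs {len(v)} values")
            if len(t) > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"channel {name}: timestamps not strictly increasing")
            self.channels[name] = (t, v)
            if self.rates.get(name, 1.0) <= 0:
                raise ValueError(f"channel {name}: nonpositive rate")
        if self.labels is not None:
            for name, lab in self.labels.items():
                lab = np.asarray(lab, dtype=int)
                if len(lab) != len(self.channels[name][0]):
                    raise ValueError(f"channel {name}: label length mismatch")
                self.labels[name] = lab

    @property
    def channel_names(self) -> list[str]:
        return sorted(self.channels)

    def n_samples(self, channel: str) -> int:
        return len(self.channels[channel][0])


@dataclass
class MinMaxScaler:
    """Per-channel affine scaling constants, retained for inversion."""

    mins: dict[str, float]
    maxs: dict[str, float]

    def inverse(self, stream: RecordingStream) -> RecordingStream:
        channels = {}
        for name, (t, v) in stream.channels.items():
            lo, hi = self.mins[name], self.maxs[name]
            if hi > lo:
                channels[name] = (t.copy(), v * (hi - lo) + lo)
            else:
                channels[name] = (t.copy(), np.full_like(v, lo))
        return RecordingStream(
            subject=stream.subject,
            channels=channels,
            rates=dict(stream.rates),
            labels=None if stream.labels is None else {k: a.copy() for k, a in stream.labels.items()},
        )


def minmax_scale(stream: RecordingStream) -> tuple[RecordingStream, MinMaxScaler]:
    """Map each channel to [0, 1] by ``(x - min) / (max - min)``.

    Constant channels are mapped to 0.5 with a warning (symmetric neutral
    value, avoids a divide by zero).  Returns the scaled stream and the
    scaler for inversion.
    """
    channels = {}
    mins: dict[str, float] = {}
    maxs: dict[str, float] = {}
    for name, (t, v) in stream.channels.items():
        lo = float(np.min(v))
        hi = float(np.max(v))
        mins[name], maxs[name] = lo, hi
        if hi > lo:
            channels[name] = (t.copy(), (v - lo) / (hi - lo))
        else:
            warnings.warn(f"channel {name} is constant; emitting 0.5", stacklevel=2)
            channels[name] = (t.copy(), np.full_like(v, 0.5))
    scaled = RecordingStream(
        subject=stream.subject,
        channels=channels,
        rates=dict(stream.rates),
        labels=None if stream.labels is None else {k: a.copy() for k, a in stream.labels.items()},
    )
    return scaled, MinMaxScaler(mins=mins, maxs=maxs)


def resample_channel(
    timestamps: np.ndarray,
    values: np.ndarray,
    target_rate: float,
    method: str = "linear_interp",
) -> tuple[np.ndarray, np.ndarray]:
    """Resample one channel onto a uniform grid spanning [t_first, t_last].

    ``linear_interp`` evaluates the piecewise-linear signal at the grid
    points; ``block_mean`` averages the native samples falling into each
    half-open target interval (empty intervals fall back to interpolation).
    """
    timestamps = np.asarray(timestamps, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(timestamps) == 0:
        raise ValueError("empty input")
    if len(timestamps) < 2:
        raise ValueError("need at least 2 samples to resample")
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    dt = 1.0 / target_rate
    n = int(np.floor((timestamps[-1] - timestamps[0]) / dt)) + 1
    grid = timestamps[0] + dt * np.arange(n)
    if method == "linear_interp":
        return grid, np.interp(grid, timestamps, values)
    if method == "block_mean":
        out = np.empty(n)
        # assign each native sample to the interval [grid_i, grid_i + dt)
        idx = np.clip(((timestamps - grid[0]) / dt).astype(int), 0, n - 1)
        counts = np.bincount(idx, minlength=n)
        sums = np.bincount(idx, weights=values, minlength=n)
        nonempty = counts > 0
        out[nonempty] = sums[nonempty] / counts[nonempty]
        if not np.all(nonempty):
            out[~nonempty] = np.interp(grid[~nonempty], timestamps, values)
        return grid, out
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

_TIME_COLUMNS = ("datetime", "timestamp", "time")


def _parse_time_column(col: pd.Series) -> np.ndarray:
    """Wall-clock datetimes or plain numbers -> seconds since first sample."""
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().all():
        t = numeric.to_numpy(dtype=float)
    else:
        parsed = pd.to_datetime(col, errors="coerce", format="mixed")
        if parsed.isna().any():
            raise ValueError("unparseable timestamps")
        t = (parsed - parsed.iloc[0]).dt.total_seconds().to_numpy()
        return t
    return t - t[0] if len(t) and t[0] != 0 else t


def _estimate_rate(t: np.ndarray, registry: ChannelRegistry, name: str) -> float:
    if len(t) >= 2:
        dt = float(np.median(np.diff(t)))
        if dt > 0:
            return 1.0 / dt
    return registry.expected_rates.get(name, 1.0)


def _interpolate_gaps(
    t: np.ndarray, v: np.ndarray, lab: np.ndarray | None, delta: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Fill interior holes in an otherwise-regular grid, never across gaps > delta."""
    if len(t) < 3:
        return t, v, lab
    diffs = np.diff(t)
    positive = diffs[diffs > 0]
    if len(positive) == 0:
        return t, v, lab
    # the smallest positive spacing is the native grid step; the median would
    # be biased upward on short reads where holes dominate
    dt = float(np.min(positive))
    new_t = [t[0]]
    new_v = [v[0]]
    new_l = [lab[0]] if lab is not None else None
    for i in range(1, len(t)):
        gap = t[i] - t[i - 1]
        k = int(round(gap / dt))
        if 2 <= k and gap <= delta and abs(gap - k * dt) < 0.25 * dt:
            for j in range(1, k):
                tj = t[i - 1] + j * dt
                new_t.append(tj)
                new_v.append(np.interp(tj, [t[i - 1], t[i]], [v[i - 1], v[i]]))
                if new_l is not None:
                    new_l.append(lab[i - 1])
        new_t.append(t[i])
        new_v.append(v[i])
        if new_l is not None:
            new_l.append(lab[i])
    return (
        np.asarray(new_t, dtype=float),
        np.asarray(new_v, dtype=float),
        None if new_l is None else np.asarray(new_l, dtype=int),
    )


def read_wide_csv(
    path,
    registry: ChannelRegistry | None = None,
    delta: float = DEFAULT_GAP_S,
    interpolate: bool = True,
) -> list[RecordingStream]:
    """Read a wide CSV (one column per channel) into one stream per subject.

    Non-numeric cells become missing and are dropped per channel; interior
    missing samples are linearly interpolated within a session, never across
    gaps larger than ``delta`` seconds.
    """
    registry = registry or ChannelRegistry()
    df = pd.read_csv(path)
    time_col = next((c for c in df.columns if c.strip().lower() in _TIME_COLUMNS), None)
    if time_col is None:
        raise ValueError("no datetime/timestamp column found")
    channel_cols = {c: registry.canonical(c) for c in df.columns}
    channel_cols = {c: name for c, name in channel_cols.items() if name is not None}
    if not channel_cols:
        raise ValueError("no recognizable channel columns")
    label_col = next((c for c in df.columns if c.strip().lower() == "label"), None)
    id_col = next((c for c in df.columns if c.strip().lower() == "id"), None)

    streams = []
    groups = df.groupby(id_col, sort=True) if id_col is not None else [("subject0", df)]
    for subject, sub in groups:
        sub = sub.reset_index(drop=True)
        t_all = _parse_time_column(sub[time_col])
        channels: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        rates: dict[str, float] = {}
        labels: dict[str, np.ndarray] | None = {} if label_col is not None else None
        lab_all = (
            pd.to_numeric(sub[label_col], errors="coerce").to_numpy()
            if label_col is not None
            else None
        )
        for col, name in channel_cols.items():
            vals = pd.to_numeric(sub[col], errors="coerce").to_numpy(dtype=float)
            mask = ~np.isnan(vals)
            t, v = t_all[mask], vals[mask]
            if len(t) == 0:
                continue
            lab = None
            if lab_all is not None:
                lab = np.nan_to_num(lab_all[mask], nan=-1.0).astype(int)
            if interpolate:
                t, v, lab = _interpolate_gaps(t, v, lab, delta)
            channels[name] = (t, v)
            rates[name] = _estimate_rate(t, registry, name)
            if labels is not None and lab is not None:
                labels[name] = lab
        streams.append(
            RecordingStream(subject=str(subject), channels=channels, rates=rates, labels=labels)
        )
    return streams


def write_wide_csv(path, streams: list[RecordingStream] | RecordingStream) -> None:
    """Write streams as a wide CSV, outer-joining channels on the timestamp.

    Cells where a channel has no sample are left blank, so per-channel native
    rates survive a read round trip losslessly.
    """
    if isinstance(streams, RecordingStream):
        streams = [streams]
    frames = []
    for stream in streams:
        pieces = []
        for name, (t, v) in stream.channels.items():
            cols = {"datetime": t, name: v}
            if stream.labels is not None and name in stream.labels:
                cols["label"] = stream.labels[name]
            pieces.append(pd.DataFrame(cols).set_index("datetime"))
        merged = pieces[0]
        for piece in pieces[1:]:
            if "label" in merged.columns and "label" in piece.columns:
                piece = piece.drop(columns="label")
            merged = merged.join(piece, how="outer")
        merged = merged.sort_index().reset_index()
        if "label" in merged.columns:
            merged["label"] = merged["label"].ffill().bfill()
        merged["id"] = stream.subject
        frames.append(merged)
    out = pd.concat(frames, ignore_index=True)
    # repr-precision floats keep the round trip below 1e-9
    out.to_csv(path, index=False, float_format="%.12g")


def read_long_csv(path, registry: ChannelRegistry | None = None) -> list[RecordingStream]:
    """Read a long CSV ``id,datetime,channel,value,label`` into streams."""
    registry = registry or ChannelRegistry()
    df = pd.read_csv(path)
    required = {"id", "channel", "value"}
    if not required.issubset({c.strip().lower() for c in df.columns}):
        raise ValueError("long CSV needs columns id, datetime, channel, value")
    df.columns = [c.strip().lower() for c in df.columns]
    streams = []
    for subject, sub in df.groupby("id", sort=True):
        channels: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        rates: dict[str, float] = {}
        labels: dict[str, np.ndarray] = {}
        for ch, chdf in sub.groupby("channel", sort=True):
            t = _parse_time_column(chdf["datetime"].reset_index(drop=True))
            order = np.argsort(t, kind="stable")
            t = t[order]
            v = chdf["value"].to_numpy(dtype=float)[order]
            channels[str(ch)] = (t, v)
            rates[str(ch)] = _estimate_rate(t, registry, str(ch))
            if "label" in chdf.columns and chdf["label"].notna().all():
                labels[str(ch)] = chdf["label"].to_numpy(dtype=int)[order]
        streams.append(
            RecordingStream(
                subject=str(subject),
                channels=channels,
                rates=rates,
                labels=labels or None,
            )
        )
    return streams


def write_long_csv(path, streams: list[RecordingStream] | RecordingStream) -> None:
    if isinstance(streams, RecordingStream):
        streams = [streams]
    buf = io.StringIO()
    buf.write("id,datetime,channel,value,label\n")
    for stream in streams:
        for name in stream.channel_names:
            t, v = stream.channels[name]
            lab = stream.labels.get(name) if stream.labels else None
            for i in range(len(t)):
                lv = "" if lab is None else str(int(lab[i]))
                buf.write(f"{stream.subject},{t[i]:.12g},{name},{v[i]:.12g},{lv}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
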