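"""Session segmentation by time gaps and fixed-length overlapping windows.

A *session* is a maximal run of samples on the reference channel with no
inter-sample gap exceeding ``delta`` seconds (default 900 s = 15 min); the
reference channel is the slowest-rate channel present, the most conservative
choice for gap detection.  Windows are half-open ``[start, start + length)``
slices in session-relative seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mmfd.signals_io import RecordingStream

__all__ = ["Session", "Window", "segment_sessions", "make_windows", "windows_from_stream"]

DEFAULT_DELTA_S = 900.0


@dataclass
class Session:
    """One continuous monitoring period of a single subject."""

    subject: str
    channels: dict[str, tuple[np.ndarray, np.ndarray]]  # session-relative timestamps
    rates: dict[str, float]
    start_s: float  # offset of the session within the parent stream
    label: int | None = None

    @property
    def duration_s(self) -> float:
        """Sample extent: last timestamp + one sample period, maximised over channels."""
        return max(
            float(t[-1]) + 1.0 / self.rates[name]
            for name, (t, _) in self.channels.items()
            if len(t)
        )


@dataclass
class Window:
    """Fixed-duration multichannel slice at native per-channel rates."""

    subject: str
    start_s: float
    length_s: float
    channels: dict[str, np.ndarray]
    rates: dict[str, float]
    label: int | None = None
    provenance: str = "real"  # real | jitter | smote
    meta: dict = field(default_factory=dict)

    @property
    def channel_names(self) -> list[str]:
        return sorted(self.channels)


def _reference_channel(stream: RecordingStream) -> str:
    if not stream.channels:
        raise ValueError("empty stream")
    return min(stream.rates, key=lambda name: (stream.rates[name], name))


def segment_sessions(stream: RecordingStream, delta: float = DEFAULT_DELTA_S) -> list[Session]:
    """Split a stream into sessions wherever consecutive reference-channel
    timestamps differ by more than ``delta`` seconds.

    All channels are cut at the same wall-clock boundaries (midpoints of the
    detected gaps); the union of sessions recovers the stream.
    """
    ref = _reference_channel(stream)
    t_ref, _ = stream.channels[ref]
    if len(t_ref) == 0:
        raise ValueError("empty reference channel")

    gap_idx = np.flatnonzero(np.diff(t_ref) > delta)
    # cut between sessions at gap midpoints so faster channels that extend a
    # little past the last reference sample stay with their session
    cuts = [(t_ref[i] + t_ref[i + 1]) / 2.0 for i in gap_idx]
    bounds = [-np.inf, *cuts, np.inf]

    sessions = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        ref_mask = (t_ref > lo) & (t_ref <= hi) if np.isfinite(hi) else (t_ref > lo)
        if not np.any(ref_mask):
            continue
        channels: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        start = None
        label = None
        for name, (t, v) in stream.channels.items():
            mask = (t > lo) & (t <= hi)
            if not np.any(mask):
                continue
            ts = t[mask]
            if start is None or ts[0] < start:
                start = float(ts[0])
            channels[name] = (ts, v[mask])
            if label is None and stream.labels and name in stream.labels:
                labs = stream.labels[name][mask]
                vals, counts = np.unique(labs, return_counts=True)
                label = int(vals[np.argmax(counts)])
        channels = {
            name: (ts - start, vs) for name, (ts, vs) in channels.items()
        }
        sessions.append(
            Session(
                subject=stream.subject,
                channels=channels,
                rates={name: stream.rates[name] for name in channels},
                start_s=start,
                label=label,
            )
        )
    return sessions


def make_windows(
    session: Session,
    length_s: float = 60.0,
    overlap: float = 0.5,
    completeness_fraction: float = 0.95,
) -> list[Window]:
    """Cut fixed-length overlapping windows out of a session.

    Window starts are ``0, (1 - overlap) * length_s, 2 * (1 - overlap) *
    length_s, ...``; a window is emitted only if every channel holds at least
    ``completeness_fraction * rate * length_s`` samples inside it.
    """
    if length_s <= 0:
        raise ValueError("length_s must be positive")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    step = (1.0 - overlap) * length_s
    duration = session.duration_s
    windows: list[Window] = []
    start = 0.0
    eps = 1e-9
    while start + length_s <= duration + eps:
        chans: dict[str, np.ndarray] = {}
        ok = True
        for name, (t, v) in session.channels.items():
            lo = np.searchsorted(t, start - eps, side="left")
            hi = np.searchsorted(t, start + length_s - eps, side="left")
            samples = v[lo:hi]
            needed = completeness_fraction * session.rates[name] * length_s
            if len(samples) < needed:
                ok = False
                break
            chans[name] = samples
        if ok:
            windows.append(
                Window(
                    subject=session.subject,
                    start_s=session.start_s + start,
                    length_s=length_s,
                    channels=chans,
                    rates=dict(session.rates),
                    label=session.label,
                )
            )
        start += step
    return windows


def windows_from_stream(
    stream: RecordingStream,
    delta: float = DEFAULT_DELTA_S,
    length_s: float = 60.0,
    overlap: float = 0.5,
    completeness_fraction: float = 0.95,
) -> list[Window]:
    """segment_sessions + make_windows over every session of one stream."""
    out: list[Window] = []
    for session in segment_sessions(stream, delta=delta):
        out.extend(
            make_windows(
                session,
                length_s=length_s,
                overlap=overlap,
                completeness_fraction=completeness_fraction,
            )
        )
    return out
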