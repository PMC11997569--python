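"""Synthetic multirate wearable recordings with known 3-class structure.

Each channel is a noisy tone: ``value(t) = mean + A * sin(2*pi*f*t + phi) +
N(0, noise_sd^2)``, with the phase drawn per session so windows are not
phase-locked.  Class structure is injected through per-class channel
parameters; :class:`ClassSeparabilityDesign` builds parameter sets where one
class pair differs only in baseline mean (time-separable) and another pair
differs only in oscillation frequency (frequency-separable), which makes the
single-branch/full-model ablation ordering a provable property of the data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from mmfd.signals_io import ChannelRegistry, RecordingStream

__all__ = [
    "ChannelParams",
    "SynthSpec",
    "ClassSeparabilityDesign",
    "default_design",
    "generate_recording",
    "generate_dataset",
]

_CLASSES = (0, 1, 2)


@dataclass(frozen=True)
class ChannelParams:
    """Per-class, per-channel tone parameters."""

    mean: float = 0.0
    sd: float = 0.0  # reserved: slow baseline wander sd (unused by default)
    amplitude: float = 0.0
    frequency: float = 0.0  # Hz


@dataclass
class SynthSpec:
    """Recipe for one synthetic recording set."""

    n_subjects: int = 3
    session_lengths_s: list[float] = field(default_factory=lambda: [1800.0, 1800.0])
    inter_session_gap_s: float = 1800.0
    channel_rates: dict[str, float] = field(
        default_factory=lambda: dict(ChannelRegistry().expected_rates)
    )
    class_params: dict[int, dict[str, ChannelParams]] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.channel_rates.values()):
            raise ValueError("all channel rates must be positive")
        if self.inter_session_gap_s <= 900:
            raise ValueError("inter_session_gap_s must exceed the 900 s session threshold")
        for label in self.class_params:
            if label not in _CLASSES:
                raise ValueError(f"class label {label} not in {_CLASSES}")


@dataclass
class ClassSeparabilityDesign:
    """Which class pairs are separable in which domain.

    ``time_separable_pair`` differs only in per-channel baseline mean;
    ``freq_separable_pair`` has identical means, sds and amplitudes and
    differs only in oscillation frequency.
    """

    time_separable_pair: tuple[int, int] = (0, 1)
    freq_separable_pair: tuple[int, int] = (1, 2)

    def validate(self, class_params: dict[int, dict[str, ChannelParams]]) -> None:
        a, b = self.freq_separable_pair
        differs = False
        for ch in class_params[a]:
            pa, pb = class_params[a][ch], class_params[b][ch]
            if (pa.mean, pa.sd, pa.amplitude) != (pb.mean, pb.sd, pb.amplitude):
                raise ValueError(
                    f"freq-separable pair {a}/{b}: channel {ch} differs in mean/sd/amplitude"
                )
            if pa.frequency != pb.frequency:
                differs = True
        if not differs:
            raise ValueError(f"freq-separable pair {a}/{b}: no frequency difference")
        a, b = self.time_separable_pair
        differs = False
        for ch in class_params[a]:
            pa, pb = class_params[a][ch], class_params[b][ch]
            if (pa.frequency, pa.amplitude) != (pb.frequency, pb.amplitude):
                raise ValueError(
                    f"time-separable pair {a}/{b}: channel {ch} differs in frequency/amplitude"
                )
            if pa.mean != pb.mean:
                differs = True
        if not differs:
            raise ValueError(f"time-separable pair {a}/{b}: no mean difference")


def default_design() -> tuple[SynthSpec, ClassSeparabilityDesign]:
    """Default 3-class design.

    Classes 0 vs 1 differ only in HR/EDA baseline mean (time-separable);
    classes 1 vs 2 differ only in the EDA tone frequency, 0.2 Hz vs 0.4 Hz at
    equal amplitude (frequency-separable).  Both tone frequencies complete an
    integer number of cycles per 5 s sub-frame at the 4 Hz EDA rate, so
    sub-frame mean and sd are exactly equal between the pair and the
    frequency identity cannot leak into time-domain statistics.
    """
    base = {
        "ACC_X": ChannelParams(mean=0.0, amplitude=0.5, frequency=1.6),
        "ACC_Y": ChannelParams(mean=0.0, amplitude=0.5, frequency=1.6),
        "ACC_Z": ChannelParams(mean=9.8, amplitude=0.2, frequency=1.6),
        "TEMP": ChannelParams(mean=33.0, amplitude=0.2, frequency=0.2),
        "HR": ChannelParams(mean=70.0, amplitude=0.0, frequency=0.0),
        "EDA": ChannelParams(mean=2.0, amplitude=0.3, frequency=0.2),
    }

    def variant(**overrides: ChannelParams) -> dict[str, ChannelParams]:
        params = dict(base)
        params.update(overrides)
        return params

    # frequencies complete whole cycles per 5 s sub-frame and land exactly on
    # the 60-bin spectral grid for their channel rates, so the frequency
    # contrast is invisible to sub-frame statistics yet sharp in the spectrum
    class_params = {
        0: variant(),
        1: variant(
            HR=ChannelParams(mean=85.0, amplitude=0.0, frequency=0.0),
            EDA=ChannelParams(mean=4.0, amplitude=0.3, frequency=0.2),
        ),
        2: variant(
            HR=ChannelParams(mean=85.0, amplitude=0.0, frequency=0.0),
            EDA=ChannelParams(mean=4.0, amplitude=0.3, frequency=0.4),
            TEMP=ChannelParams(mean=33.0, amplitude=0.2, frequency=0.6),
            ACC_X=ChannelParams(mean=0.0, amplitude=0.5, frequency=3.2),
        ),
    }
    noise_sd = {
        "ACC_X": 0.2,
        "ACC_Y": 0.2,
        "ACC_Z": 0.2,
        "TEMP": 0.05,
        "HR": 1.0,
        "EDA": 0.1,
    }
    spec = SynthSpec(class_params=class_params, noise_sd=noise_sd)
    design = ClassSeparabilityDesign()
    design.validate(class_params)
    return spec, design


def _subject_rng(spec: SynthSpec, subject: str, class_label: int) -> np.random.Generator:
    # derive an independent, reproducible stream per (seed, subject, label);
    # crc32 (not hash()) so the derivation survives PYTHONHASHSEED changes
    digest = zlib.crc32(subject.encode())
    ss = np.random.SeedSequence([spec.seed, int(class_label), digest])
    return np.random.default_rng(ss)


def generate_recording(spec: SynthSpec, subject: str, class_label: int) -> RecordingStream:
    """Generate one subject's recording for a single stress class.

    Sessions are separated by ``inter_session_gap_s``; every sample carries
    ``class_label``.  Identical ``(spec, subject, class_label, seed)`` yield
    bit-identical output.
    """
    if class_label not in _CLASSES:
        raise ValueError(f"class_label must be one of {_CLASSES}")
    if class_label not in spec.class_params:
        raise ValueError(f"spec has no parameters for class {class_label}")
    params = spec.class_params[class_label]
    for ch in params:
        if ch not in spec.channel_rates:
            raise ValueError(f"unknown channel name {ch!r}")

    rng = _subject_rng(spec, subject, class_label)
    channel_names = sorted(params)
    channels: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    labels: dict[str, np.ndarray] = {}

    session_starts = []
    t0 = 0.0
    for length in spec.session_lengths_s:
        session_starts.append(t0)
        t0 += length + spec.inter_session_gap_s

    # one phase draw per (session, channel), in a fixed order for determinism
    phases = {
        (si, ch): rng.uniform(0.0, 2.0 * np.pi)
        for si in range(len(spec.session_lengths_s))
        for ch in channel_names
    }

    for ch in channel_names:
        rate = spec.channel_rates[ch]
        p = params[ch]
        sd = spec.noise_sd.get(ch, 0.0)
        ts, vs = [], []
        for si, (start, length) in enumerate(zip(session_starts, spec.session_lengths_s)):
            n = int(round(length * rate))
            t = start + np.arange(n) / rate
            v = p.mean + p.amplitude * np.sin(2 * np.pi * p.frequency * t + phases[si, ch])
            if sd > 0:
                v = v + rng.normal(0.0, sd, size=n)
            ts.append(t)
            vs.append(v)
        t = np.concatenate(ts)
        v = np.concatenate(vs)
        channels[ch] = (t, v)
        labels[ch] = np.full(len(t), class_label, dtype=int)

    return RecordingStream(
        subject=subject,
        channels=channels,
        rates={ch: spec.channel_rates[ch] for ch in channel_names},
        labels=labels,
    )


def generate_dataset(
    spec: SynthSpec, design: ClassSeparabilityDesign, n_per_class: int
) -> list[RecordingStream]:
    """Generate a balanced list of streams, ``n_per_class`` per stress class."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    design.validate(spec.class_params)
    streams = []
    for label in _CLASSES:
        for i in range(n_per_class):
            streams.append(generate_recording(spec, f"S{label}_{i:03d}", label))
    return streams
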