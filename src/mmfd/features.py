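"""Dual-domain feature extraction: sub-frame statistics and binned spectra.

Each 60 s window becomes two tensors:

* time branch  — the window is split into ``T`` contiguous sub-frames
  (default 12, i.e. 5 s each) and per-channel statistics (mean, sd, min, max
  by default) are computed per sub-frame, giving a ``T x (channels * stats)``
  block.  The sd uses the population form ``sqrt(mean((x - mu)^2))``.
* frequency branch — per channel, the log-compressed magnitude spectrum
  ``log(1 + |X_k|)`` with the DC bin excluded, linearly interpolated onto a
  common ``F``-bin axis (default 64) over each channel's normalized
  frequencies ``(0, Nyquist]``.  Excluding DC keeps window means in the time
  branch only, so the two branches carry disjoint information.

Standardization (z-scoring per scalar feature position) is fitted on
training rows only and reapplied to held-out rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mmfd.preprocess import Window

__all__ = [
    "FeatureConfig",
    "FeatureDataset",
    "FeatureScaler",
    "time_stats",
    "rmssd",
    "dft",
    "band_powers",
    "window_time_block",
    "window_freq_block",
    "build_feature_dataset",
    "standardize_features",
]

_STAT_FUNCS = {
    "mean": lambda x: float(np.mean(x)),
    "std": lambda x: float(np.sqrt(np.mean((x - np.mean(x)) ** 2))),
    "min": lambda x: float(np.min(x)),
    "max": lambda x: float(np.max(x)),
    "p10": lambda x: float(np.percentile(x, 10)),
    "p25": lambda x: float(np.percentile(x, 25)),
    "p50": lambda x: float(np.percentile(x, 50)),
    "p75": lambda x: float(np.percentile(x, 75)),
    "p90": lambda x: float(np.percentile(x, 90)),
}


@dataclass(frozen=True)
class FeatureConfig:
    n_subframes: int = 12
    stats: tuple[str, ...] = ("mean", "std", "min", "max")
    n_freq_bins: int = 64
    include_hrv: bool = False  # append window-level HR sd + RMSSD as two extra columns

    def __post_init__(self) -> None:
        unknown = set(self.stats) - set(_STAT_FUNCS)
        if unknown:
            raise ValueError(f"unknown stats: {sorted(unknown)}")
        if self.n_subframes < 1 or self.n_freq_bins < 1:
            raise ValueError("n_subframes and n_freq_bins must be >= 1")


@dataclass
class FeatureScaler:
    """Per-scalar-position z-scoring state, fitted on training rows only."""

    t_mean: np.ndarray
    t_sd: np.ndarray
    f_mean: np.ndarray
    f_sd: np.ndarray

    def transform(self, X_t: np.ndarray, X_f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t_sd = np.where(self.t_sd > 0, self.t_sd, 1.0)
        f_sd = np.where(self.f_sd > 0, self.f_sd, 1.0)
        # constant features map to exactly 0
        Zt = np.where(self.t_sd > 0, (X_t - self.t_mean) / t_sd, 0.0)
        Zf = np.where(self.f_sd > 0, (X_f - self.f_mean) / f_sd, 0.0)
        return Zt, Zf


@dataclass
class FeatureDataset:
    """Paired branch tensors: ``X_t (B,T,F_t)``, ``X_f (B,F,F_f)``, labels ``y``."""

    X_t: np.ndarray
    X_f: np.ndarray
    y: np.ndarray
    provenance: np.ndarray  # per-row flag: real | jitter | smote
    meta: dict = field(default_factory=dict)
    scaler: FeatureScaler | None = None

    def __post_init__(self) -> None:
        if not (len(self.X_t) == len(self.X_f) == len(self.y) == len(self.provenance)):
            raise ValueError("inconsistent batch dimension")

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx: np.ndarray) -> "FeatureDataset":
        return FeatureDataset(
            X_t=self.X_t[idx],
            X_f=self.X_f[idx],
            y=self.y[idx],
            provenance=self.provenance[idx],
            meta=dict(self.meta),
            scaler=self.scaler,
        )


def time_stats(samples: np.ndarray, stats: tuple[str, ...] = ("mean", "std", "min", "max")) -> np.ndarray:
    """Statistics of one sample array; sd is the population form."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty input")
    return np.array([_STAT_FUNCS[s](samples) for s in stats])


def rmssd(samples: np.ndarray) -> float:
    """Root mean square of successive differences (0 for length < 2)."""
    samples = np.asarray(samples, dtype=float)
    if len(samples) < 2:
        return 0.0
    d = np.diff(samples)
    return float(np.sqrt(np.mean(d**2)))


def dft(samples: np.ndarray) -> np.ndarray:
    """Full complex spectrum ``X_k = sum_n x_n e^{-j 2 pi k n / N}``.

    Computed with a fast transform but contracted to the direct summation
    definition (tests compare against an O(N^2) oracle).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 1:
        raise ValueError("need at least 1 sample")
    return np.fft.fft(samples)


def band_powers(spectrum: np.ndarray, rate: float, n_bands: int) -> np.ndarray:
    """Sum of ``|X_k|^2`` over ``n_bands`` equal normalized-frequency bands.

    Uses bins ``k = 1 .. floor(N/2)`` (DC excluded); band ``b`` covers
    normalized frequencies ``(b/n_bands, (b+1)/n_bands]`` of Nyquist.
    """
    spectrum = np.asarray(spectrum)
    n = len(spectrum)
    half = n // 2
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if n_bands > half:
        raise ValueError("n_bands exceeds the number of positive-frequency bins")
    k = np.arange(1, half + 1)
    frac = k / half  # (0, 1]
    band = np.minimum((np.ceil(frac * n_bands) - 1).astype(int), n_bands - 1)
    powers = np.abs(spectrum[1 : half + 1]) ** 2
    return np.bincount(band, weights=powers, minlength=n_bands)


def _subframe_split(samples: np.ndarray, n_subframes: int) -> list[np.ndarray]:
    if len(samples) < n_subframes:
        raise ValueError("window too short for requested sub-frames")
    return np.array_split(samples, n_subframes)


def window_time_block(window: Window, config: FeatureConfig) -> np.ndarray:
    """Time-branch block for one window: shape (T, channels*stats [+2 HRV])."""
    names = window.channel_names
    n_stats = len(config.stats)
    n_cols = len(names) * n_stats + (2 if config.include_hrv and "HR" in names else 0)
    block = np.empty((config.n_subframes, n_cols))
    for ci, name in enumerate(names):
        frames = _subframe_split(window.channels[name], config.n_subframes)
        for ti, frame in enumerate(frames):
            block[ti, ci * n_stats : (ci + 1) * n_stats] = time_stats(frame, config.stats)
    if config.include_hrv and "HR" in names:
        hr_frames = _subframe_split(window.channels["HR"], config.n_subframes)
        base = len(names) * n_stats
        for ti, frame in enumerate(hr_frames):
            block[ti, base] = _STAT_FUNCS["std"](frame)
            block[ti, base + 1] = rmssd(frame)
    return block


def window_freq_block(window: Window, config: FeatureConfig) -> np.ndarray:
    """Frequency-branch block for one window: shape (F, channels).

    Per channel: log(1+|X_k|) for k = 1..floor(N/2), interpolated onto
    ``n_freq_bins`` bins at normalized frequencies j/F for j = 1..F.
    """
    names = window.channel_names
    F = config.n_freq_bins
    block = np.empty((F, len(names)))
    target = np.arange(1, F + 1) / F  # (0, 1]
    for ci, name in enumerate(names):
        x = window.channels[name]
        spec = np.fft.rfft(x)
        half = len(x) // 2
        mags = np.log1p(np.abs(spec[1 : half + 1]))
        axis = np.arange(1, half + 1) / half
        block[:, ci] = np.interp(target, axis, mags)
    return block


def build_feature_dataset(windows: list[Window], config: FeatureConfig | None = None) -> FeatureDataset:
    """Extract both branch tensors from a list of windows (order preserved)."""
    if not windows:
        raise ValueError("no windows")
    config = config or FeatureConfig()
    names = windows[0].channel_names
    for win in windows:
        if win.channel_names != names:
            raise ValueError("windows do not share a channel set")
    X_t = np.stack([window_time_block(w, config) for w in windows])
    X_f = np.stack([window_freq_block(w, config) for w in windows])
    y = np.array([-1 if w.label is None else int(w.label) for w in windows])
    prov = np.array([w.provenance for w in windows])
    col_names = [f"{ch}:{st}" for ch in names for st in config.stats]
    if config.include_hrv and "HR" in names:
        col_names += ["HR:hrv_sd", "HR:rmssd"]
    meta = {
        "channels": names,
        "stats": list(config.stats),
        "time_columns": col_names,
        "n_subframes": config.n_subframes,
        "n_freq_bins": config.n_freq_bins,
    }
    return FeatureDataset(X_t=X_t, X_f=X_f, y=y, provenance=prov, meta=meta)


def standardize_features(dataset: FeatureDataset, fit_rows: np.ndarray) -> FeatureDataset:
    """Z-score every scalar feature position using statistics of ``fit_rows``.

    Positions with zero sd over the fit rows map to exactly 0.  The fitted
    scaler is stored on the returned dataset for reuse on held-out rows.
    """
    fit_rows = np.asarray(fit_rows)
    if fit_rows.size == 0:
        raise ValueError("fit_rows is empty")
    scaler = FeatureScaler(
        t_mean=dataset.X_t[fit_rows].mean(axis=0),
        t_sd=dataset.X_t[fit_rows].std(axis=0),
        f_mean=dataset.X_f[fit_rows].mean(axis=0),
        f_sd=dataset.X_f[fit_rows].std(axis=0),
    )
    Zt, Zf = scaler.transform(dataset.X_t, dataset.X_f)
    return FeatureDataset(
        X_t=Zt,
        X_f=Zf,
        y=dataset.y.copy(),
        provenance=dataset.provenance.copy(),
        meta=dict(dataset.meta),
        scaler=scaler,
    )
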