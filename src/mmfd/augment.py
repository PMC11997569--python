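"""Training-set augmentation: dense sliding windows and Gaussian jittering.

Augmentation only ever touches the training split; calling
:func:`augment_training_set` on windows marked as belonging to an eval/test
split raises, and every synthetic window carries a provenance flag so the
pipeline can audit split purity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from mmfd.preprocess import Window

__all__ = ["AugmentSpec", "sliding_windows", "jitter", "jitter_window", "augment_training_set"]


@dataclass(frozen=True)
class AugmentSpec:
    w: int = 0  # dense re-windowing size in samples; 0 disables
    s: int = 1  # dense re-windowing step in samples
    jitter_sd: float = 0.02  # scaled-signal units
    n_jitter_copies: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.w and not (1 <= self.s <= self.w):
            raise ValueError("need 1 <= s <= w")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.n_jitter_copies < 0:
            raise ValueError("n_jitter_copies must be >= 0")


def sliding_windows(segment: np.ndarray, w: int, s: int) -> list[np.ndarray]:
    """All length-``w`` windows starting at 1-based indices 1, 1+s, 1+2s, ...

    Returns ``floor((n - w) / s) + 1`` windows, or an empty list when the
    segment is shorter than ``w``.
    """
    if not (1 <= s <= w):
        raise ValueError("need 1 <= s <= w")
    segment = np.asarray(segment)
    n = len(segment)
    if w > n:
        return []
    return [segment[j : j + w] for j in range(0, n - w + 1, s)]


def jitter(window: np.ndarray, sigma: float, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Add i.i.d. Gaussian noise ``N(0, sigma^2)`` to each sample."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    window = np.asarray(window, dtype=float)
    if sigma == 0:
        return window.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return window + rng.normal(0.0, sigma, size=window.shape)


def jitter_window(window: Window, sigma: float, rng: np.random.Generator) -> Window:
    """Jitter every channel of a multichannel window; label preserved."""
    channels = {name: jitter(vals, sigma, rng) for name, vals in sorted(window.channels.items())}
    return replace(window, channels=channels, provenance="jitter")


def augment_training_set(windows: list[Window], spec: AugmentSpec) -> list[Window]:
    """originals + ``n_jitter_copies`` jittered copies per original.

    Raises if any input window is flagged as evaluation data (leakage guard).
    Denser multichannel windowing is done at the session level by lowering the
    windowing step in :func:`mmfd.preprocess.make_windows`;
    :func:`sliding_windows` provides the single-channel sample-level variant.
    """
    for win in windows:
        if win.meta.get("split") in ("eval", "test", "val"):
            raise ValueError("augmentation must not touch evaluation windows")
    rng = np.random.default_rng(spec.seed)
    out = list(windows)
    for win in windows:
        for _ in range(spec.n_jitter_copies):
            out.append(jitter_window(win, spec.jitter_sd, rng))
    return out
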