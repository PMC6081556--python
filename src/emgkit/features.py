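"""Sliding-window feature extraction: per-channel RMS and cross-channel MAV.

The decoder's feature stream is built from overlapping windows of length N
samples advanced by M samples (defaults 200/100 at 1 kHz, i.e. 200 ms windows
at a 100 ms step).  Each window yields a K-vector of per-channel root mean
squares

    RMS = sqrt(1/N * sum_n x[n]^2)

used for classification, and a single mean absolute value pooled over all
channels

    MAV = 1/(N K) * sum_k sum_n |x_k[n]|

used as the muscle-effort estimate for proportional control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synth import REST, EmgRecording

__all__ = [
    "WindowConfig",
    "FeatureWindow",
    "sliding_windows",
    "rms",
    "mav",
    "featurize",
    "training_set",
    "window_count",
]


@dataclass(frozen=True)
class WindowConfig:
    """Window length N and step M, in samples."""

    window_len: int = 200
    step: int = 100
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.window_len):
            raise ValueError(
                f"require 0 < step <= window_len, got step={self.step}, "
                f"window_len={self.window_len}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")

    @classmethod
    def from_ms(
        cls, window_ms: float = 200.0, step_ms: float = 100.0,
        sampling_rate: float = 1000.0,
    ) -> "WindowConfig":
        return cls(
            window_len=int(round(window_ms * sampling_rate / 1000.0)),
            step=int(round(step_ms * sampling_rate / 1000.0)),
            sampling_rate=sampling_rate,
        )


@dataclass(frozen=True)
class FeatureWindow:
    """Features of one window ending at sample index ``t_end`` (exclusive)."""

    t_end: int
    rms: np.ndarray  # (K,)
    mav: float
    label: int  # majority per-sample label; REST for rest windows

    @property
    def is_rest(self) -> bool:
        return self.label == REST


def window_count(n_samples: int, config: WindowConfig) -> int:
    """Number of fully populated windows: floor((T - N) / M) + 1, 0 if T < N."""
    if n_samples < config.window_len:
        return 0
    return (n_samples - config.window_len) // config.step + 1


def sliding_windows(recording, config: WindowConfig) -> list[tuple[int, int]]:
    """Fully populated [start, end) sample ranges in order.

    The first window covers samples [0, N); each next window starts M samples
    later.  A recording shorter than one window yields an empty list with a
    warning so that streaming start-up is well defined.
    """
    t = recording if isinstance(recording, int) else recording.n_samples
    n, m = config.window_len, config.step
    if t < n:
        warnings.warn(
            f"recording of {t} samples is shorter than one window ({n}); "
            "no features produced",
            stacklevel=2,
        )
        return []
    return [(k * m, k * m + n) for k in range(window_count(t, config))]


def rms(window) -> float:
    """Root mean square of one channel's window."""
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("rms of an empty window is undefined")
    return float(np.sqrt(np.mean(x**2)))


def mav(block) -> float:
    """Mean absolute value over an N-sample, K-channel block (all N*K values)."""
    x = np.asarray(block, dtype=float)
    if x.size == 0:
        raise ValueError("mav of an empty block is undefined")
    return float(np.mean(np.abs(x)))


def _majority_label(labels: np.ndarray) -> int:
    vals, counts = np.unique(labels, return_counts=True)
    top = vals[counts == counts.max()]
    if top.size == 1:
        return int(top[0])
    end_label = int(labels[-1])
    # tie: prefer the label at the window end, else the lowest tied label
    return end_label if end_label in top else int(top.min())


def featurize(recording: EmgRecording, config: WindowConfig) -> list[FeatureWindow]:
    """One :class:`FeatureWindow` per sliding window, in stream order.

    The window label is the majority per-sample label (ties broken by the
    label at the window end).  Rest-majority windows are kept in the stream
    (so event counts are conserved downstream) but carry ``label == REST``;
    use :func:`training_set` to drop them when building classifier data.
    """
    spans = sliding_windows(recording, config)
    out: list[FeatureWindow] = []
    for start, end in spans:
        block = recording.samples[start:end]
        rms_vec = np.sqrt(np.mean(block**2, axis=0))
        out.append(
            FeatureWindow(
                t_end=end,
                rms=rms_vec,
                mav=float(np.mean(np.abs(block))),
                label=_majority_label(recording.labels[start:end]),
            )
        )
    return out


def training_set(
    windows: list[FeatureWindow], drop_rest: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Stack feature windows into (X, y) arrays, excluding rest by default."""
    kept = [w for w in windows if not (drop_rest and w.is_rest)]
    if not kept:
        raise ValueError("no non-rest feature windows available")
    x = np.stack([w.rms for w in kept])
    y = np.array([w.label for w in kept], dtype=int)
    return x, y
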