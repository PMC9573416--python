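"""Windowing and normalization.

The 15 Hz distance trace is cut into 5 s windows with 80 % overlap (1 s
step, 75 samples per channel per window); each window's regression targets
are the time-weighted means of the breath-by-breath values overlapping it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from rmp_ee.synthetic import BreathSample, RmpTrace

__all__ = [
    "Window",
    "WindowSet",
    "ChannelScaler",
    "segment_windows",
    "align_targets",
    "normalize_signals",
]

logger = logging.getLogger(__name__)

CHANNEL_NAMES = ("rc", "ab", "cw", "sp")


@dataclass(frozen=True)
class Window:
    """One 5 s training unit: a (4, 75) signal slice plus mean targets."""

    start: float  # s
    signal: np.ndarray  # (4, window_s * fs), channel-major
    target_ee: float  # kcal/min
    target_vo2: float  # mL/min/kg
    subject_id: str = ""
    intensity_label: str | None = None
    duration: float = 5.0

    @property
    def midpoint(self) -> float:
        return self.start + self.duration / 2.0


@dataclass
class WindowSet:
    windows: list[Window]
    step: float = 1.0
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def signals(self) -> np.ndarray:
        """(n, 4, T) stacked signal array."""
        return np.stack([w.signal for w in self.windows])

    def targets(self, which: str = "ee") -> np.ndarray:
        attr = {"ee": "target_ee", "vo2": "target_vo2"}[which]
        return np.array([getattr(w, attr) for w in self.windows])

    def labels(self) -> list[str | None]:
        return [w.intensity_label for w in self.windows]

    def subject_ids(self) -> list[str]:
        return [w.subject_id for w in self.windows]


def segment_windows(trace: RmpTrace, window_s: float = 5.0,
                    overlap: float = 0.8) -> list[tuple[float, np.ndarray]]:
    """Slice the trace into overlapping windows anchored at t = 0.

    Step = window_s * (1 - overlap); the count follows the closed form
    floor((T - window_s) / step) + 1. A trace shorter than one window
    yields an empty list with a warning, not an exception.
    """
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    fs = trace.fs
    samples_per_window = int(round(window_s * fs))
    step_s = window_s * (1.0 - overlap)
    step_samples = max(int(round(step_s * fs)), 1)
    sig = trace.stack()
    n = sig.shape[1]
    if n < samples_per_window:
        warnings.warn(
            f"trace of {n / fs:.1f} s is shorter than one {window_s:.0f} s "
            "window; returning no windows", stacklevel=2)
        return []
    n_windows = (n - samples_per_window) // step_samples + 1
    out = []
    for i in range(n_windows):
        j = i * step_samples
        start = trace.t0 + j / fs
        out.append((start, sig[:, j:j + samples_per_window]))
    return out


def align_targets(segments: list[tuple[float, np.ndarray]],
                  breaths: list[BreathSample], body_mass: float,
                  subject_id: str = "", window_s: float = 5.0,
                  step: float = 1.0) -> WindowSet:
    """Pair each signal window with time-weighted mean breath targets.

    A breath spanning [t - duration, t) contributes to window
    [start, start + window_s) in proportion to the overlap of the two
    intervals. Windows overlapped by no breath are dropped (and counted in
    the WindowSet provenance).
    """
    if not breaths:
        raise ValueError("breath list must be non-empty")
    ends = np.array([b.t for b in breaths])
    starts = ends - np.array([b.duration for b in breaths])
    ee = np.array([b.ee for b in breaths])
    vo2 = np.array([b.vo2 for b in breaths])

    windows: list[Window] = []
    dropped = 0
    for w_start, sig in segments:
        w_end = w_start + window_s
        lo = int(np.searchsorted(ends, w_start, side="right"))
        hi = int(np.searchsorted(starts, w_end, side="left"))
        weights = np.minimum(ends[lo:hi], w_end) - np.maximum(starts[lo:hi], w_start)
        weights = np.clip(weights, 0.0, None)
        total = weights.sum()
        if total <= 0.0:
            dropped += 1
            continue
        windows.append(Window(
            start=w_start, signal=sig,
            target_ee=float(weights @ ee[lo:hi] / total),
            target_vo2=float(weights @ vo2[lo:hi] / total / body_mass),
            subject_id=subject_id,
        ))
    if dropped:
        logger.warning("dropped %d windows with no overlapping breath", dropped)
    return WindowSet(windows, step=step,
                     provenance={"dropped_no_breath": dropped,
                                 "window_s": window_s})


class ChannelScaler:
    """Per-channel z-scoring with an exact inverse.

    Statistics are computed from a designated source (normally the training
    split only) and then applied unchanged to every split.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, stats_source: WindowSet) -> "ChannelScaler":
        if len(stats_source) == 0:
            raise ValueError("stats_source must be non-empty")
        sig = stats_source.signals()  # (n, 4, T)
        self.mean_ = sig.mean(axis=(0, 2))
        self.sd_ = sig.std(axis=(0, 2))
        for k, s in enumerate(self.sd_):
            if s == 0.0:
                raise ValueError(
                    f"channel {CHANNEL_NAMES[k]!r} is constant; cannot z-score")
        return self

    def _check(self) -> None:
        if self.mean_ is None:
            raise RuntimeError("scaler is not fitted")

    def transform(self, windows: WindowSet) -> WindowSet:
        self._check()
        m = self.mean_[:, None]
        s = self.sd_[:, None]
        new = [replace(w, signal=(w.signal - m) / s) for w in windows]
        return WindowSet(new, step=windows.step, provenance=dict(windows.provenance))

    def inverse_transform(self, windows: WindowSet) -> WindowSet:
        self._check()
        m = self.mean_[:, None]
        s = self.sd_[:, None]
        new = [replace(w, signal=w.signal * s + m) for w in windows]
        return WindowSet(new, step=windows.step, provenance=dict(windows.provenance))


def normalize_signals(windows: WindowSet,
                      stats_source: WindowSet) -> tuple[WindowSet, ChannelScaler]:
    """Z-score every window using statistics from ``stats_source`` only."""
    scaler = ChannelScaler().fit(stats_source)
    return scaler.transform(windows), scaler
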