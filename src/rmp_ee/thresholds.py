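"""Ventilatory thresholds and intensity labelling.

During a ramp test the ventilatory equivalent for oxygen (VE/VO2) starts to
rise at the first ventilatory threshold (VTh1) while VE/VCO2 stays flat;
VE/VCO2 itself starts rising at the second threshold (VTh2). Human readers
place these breakpoints visually; here they are located by two-segment
continuous piecewise-linear least squares over candidate breakpoints — a
reproducible surrogate validated by recovery against simulator ground truth.

The thresholds split the ramp into three intensity ranges which, together
with the sitting/standing and rest phases, give the five intensity labels
used in the per-intensity agreement tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from rmp_ee.preprocessing import Window, WindowSet
from rmp_ee.synthetic import BreathSample, ProtocolPhase

__all__ = [
    "EquivalentsSeries",
    "IntensityPartition",
    "Vo2maxCriteria",
    "ThresholdError",
    "compute_equivalents",
    "detect_thresholds",
    "label_windows",
    "check_vo2max",
]

INTENSITY_LABELS = ("sitting", "standing", "rest_to_th1", "th1_to_th2",
                    "th2_to_vo2max")


class ThresholdError(ValueError):
    """Raised when no admissible threshold pair exists."""


@dataclass(frozen=True)
class EquivalentsSeries:
    t: np.ndarray  # s, end-of-breath times
    eq_o2: np.ndarray  # VE/VO2
    eq_co2: np.ndarray  # VE/VCO2
    vo2: np.ndarray  # mL/min, carried along for threshold bookkeeping

    def restrict(self, t_min: float, t_max: float) -> "EquivalentsSeries":
        m = (self.t >= t_min) & (self.t <= t_max)
        return EquivalentsSeries(self.t[m], self.eq_o2[m], self.eq_co2[m],
                                 self.vo2[m])


@dataclass(frozen=True)
class IntensityPartition:
    t_th1: float  # s
    t_th2: float  # s
    vo2_at_th1: float  # mL/min
    vo2_at_th2: float  # mL/min

    def __post_init__(self) -> None:
        if not self.t_th1 < self.t_th2:
            raise ValueError("t_th1 must precede t_th2")


@dataclass(frozen=True)
class Vo2maxCriteria:
    hr_steady_near_max: bool
    rer_gt_1_1: bool
    vo2_plateau: bool
    cadence_failure: bool
    hr_max_pred: float  # bpm, 220 - age

    @property
    def n_satisfied(self) -> int:
        return sum((self.hr_steady_near_max, self.rer_gt_1_1,
                    self.vo2_plateau, self.cadence_failure))

    @property
    def attained(self) -> bool:
        return self.n_satisfied >= 3


def compute_equivalents(breaths: list[BreathSample],
                        smooth: int = 5) -> EquivalentsSeries:
    """VE/VO2 and VE/VCO2 per breath, lightly smoothed by a moving median."""
    if not breaths:
        raise ValueError("breath list must be non-empty")
    for i, b in enumerate(breaths):
        if b.vo2 <= 0 or b.vco2 <= 0:
            raise ValueError(f"non-positive gas rate at breath {i}")
    t = np.array([b.t for b in breaths])
    ve = np.array([b.ve for b in breaths])
    vo2 = np.array([b.vo2 for b in breaths])
    vco2 = np.array([b.vco2 for b in breaths])
    eq_o2 = ve / (vo2 / 1000.0)
    eq_co2 = ve / (vco2 / 1000.0)
    if smooth and smooth > 1 and len(t) >= smooth:
        eq_o2 = median_filter(eq_o2, size=smooth, mode="nearest")
        eq_co2 = median_filter(eq_co2, size=smooth, mode="nearest")
    return EquivalentsSeries(t=t, eq_o2=eq_o2, eq_co2=eq_co2, vo2=vo2)


def _hinge_fit(t: np.ndarray, y: np.ndarray, margin: int = 5
               ) -> tuple[float, float, float, float]:
    """Best two-segment continuous piecewise-linear fit.

    Returns (breakpoint time, SSE, slope before, slope after). The
    breakpoint is searched over interior sample times with ``margin``
    points on each side; design matrix [1, t, max(0, t - tb)].
    """
    n = len(t)
    best = (np.nan, np.inf, 0.0, 0.0)
    for i in range(margin, n - margin):
        tb = t[i]
        X = np.column_stack([np.ones(n), t - t[0], np.maximum(0.0, t - tb)])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((X @ coef - y) ** 2))
        if sse < best[1]:
            best = (float(tb), sse, float(coef[1]), float(coef[1] + coef[2]))
    return best


def _line_sse(t: np.ndarray, y: np.ndarray) -> float:
    X = np.column_stack([np.ones_like(t), t])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.sum((X @ coef - y) ** 2))


def detect_thresholds(series: EquivalentsSeries, ramp: ProtocolPhase,
                      min_gain: float = 0.20,
                      stability_frac: float = 0.10) -> IntensityPartition:
    """Locate VTh1 and VTh2 on the ramp portion of the equivalents series.

    VTh2 is the breakpoint of VE/VCO2; VTh1 is the breakpoint of VE/VO2
    restricted to times before VTh2 (past VTh2 the oxygen equivalent
    steepens again and would bias a single-hinge fit). A breakpoint is
    accepted only if the hinge fit improves on a straight line by at least
    ``min_gain`` of its SSE and the post-break slope exceeds the pre-break
    slope; VE/VCO2 must additionally be stable (|slope| below
    ``stability_frac`` of the post-VTh1 VE/VO2 slope) before its own
    breakpoint. Violations raise :class:`ThresholdError`.
    """
    s = series.restrict(ramp.start, ramp.end)
    if len(s.t) < 30:
        raise ThresholdError("need at least 30 ramp breaths")

    tb2, sse2, pre2, post2 = _hinge_fit(s.t, s.eq_co2)
    line2 = _line_sse(s.t, s.eq_co2)
    if not np.isfinite(tb2) or sse2 > (1.0 - min_gain) * line2 or post2 <= pre2:
        raise ThresholdError("thresholds indeterminate: no VE/VCO2 breakpoint")

    before = s.restrict(ramp.start, tb2)
    if len(before.t) < 15:
        raise ThresholdError("thresholds indeterminate: VTh2 too early")
    tb1, sse1, pre1, post1 = _hinge_fit(before.t, before.eq_o2)
    line1 = _line_sse(before.t, before.eq_o2)
    if not np.isfinite(tb1) or sse1 > (1.0 - min_gain) * line1 or post1 <= pre1:
        raise ThresholdError("thresholds indeterminate: no VE/VO2 breakpoint")
    if abs(pre2) > stability_frac * max(post1 - pre1, 1e-12):
        raise ThresholdError(
            "thresholds indeterminate: VE/VCO2 not stable before its breakpoint")
    if not tb1 < tb2:
        raise ThresholdError("thresholds indeterminate: VTh1 not before VTh2")

    vo2_th1 = float(np.interp(tb1, s.t, s.vo2))
    vo2_th2 = float(np.interp(tb2, s.t, s.vo2))
    return IntensityPartition(t_th1=tb1, t_th2=tb2,
                              vo2_at_th1=vo2_th1, vo2_at_th2=vo2_th2)


def label_windows(windows: WindowSet, partition: IntensityPartition,
                  phases: list[ProtocolPhase]) -> WindowSet:
    """Assign one of the five intensity labels to every window.

    Labels follow the window midpoint. Ramp windows compare the midpoint
    to the thresholds with left-closed upper ranges (a midpoint exactly at
    a threshold joins the higher intensity); rest-phase windows join the
    rest-to-VTh1 range. Windows outside all phases are labelled "unknown"
    and excluded from per-intensity statistics downstream.
    """
    from dataclasses import replace

    def classify(w: Window) -> str:
        mid = w.midpoint
        for ph in phases:
            if ph.start <= mid < ph.end:
                if ph.label in ("sitting", "standing"):
                    return ph.label
                if ph.label == "rest":
                    return "rest_to_th1"
                if mid < partition.t_th1:
                    return "rest_to_th1"
                if mid < partition.t_th2:
                    return "th1_to_th2"
                return "th2_to_vo2max"
        return "unknown"

    labelled = [replace(w, intensity_label=classify(w)) for w in windows]
    return WindowSet(labelled, step=windows.step,
                     provenance=dict(windows.provenance))


def _window_mean(t: np.ndarray, y: np.ndarray, t_lo: float, t_hi: float) -> float:
    m = (t >= t_lo) & (t <= t_hi)
    return float(y[m].mean()) if m.any() else np.nan


def check_vo2max(breaths: list[BreathSample], age: float, body_mass: float,
                 hr: np.ndarray | None = None,
                 cadence_failure: bool = False,
                 ramp: ProtocolPhase | None = None) -> Vo2maxCriteria:
    """Evaluate the maximal-test attainment criteria.

    Flags: RER > 1.1 on any 30 s average; a VO2 plateau (the final minute
    rises by < 2.1 mL/kg/min over the minute before it); heart rate within
    10 bpm of the age-predicted maximum 220 - age when an HR series is
    given; a caller-supplied cadence-failure flag. Attainment requires at
    least three of the four.
    """
    hr_max_pred = 220.0 - age
    t = np.array([b.t for b in breaths])
    rer = np.array([b.rer for b in breaths])
    vo2_kg = np.array([b.vo2 for b in breaths]) / body_mass
    if ramp is not None:
        m = t >= ramp.start
        t, rer, vo2_kg = t[m], rer[m], vo2_kg[m]

    rer_flag = False
    for i in range(len(t)):
        m = (t >= t[i] - 30.0) & (t <= t[i])
        if m.sum() >= 3 and rer[m].mean() > 1.1:
            rer_flag = True
            break

    # rise across the final minute: end-of-test level vs its start
    plateau_flag = False
    if len(t) and t[-1] - t[0] >= 120.0:
        last = _window_mean(t, vo2_kg, t[-1] - 15.0, t[-1])
        first = _window_mean(t, vo2_kg, t[-1] - 60.0, t[-1] - 45.0)
        if np.isfinite(last) and np.isfinite(first):
            plateau_flag = (last - first) < 2.1

    hr_flag = bool(hr is not None and len(hr) and
                   np.max(hr) >= hr_max_pred - 10.0)
    return Vo2maxCriteria(hr_steady_near_max=hr_flag, rer_gt_1_1=rer_flag,
                          vo2_plateau=plateau_flag,
                          cadence_failure=cadence_failure,
                          hr_max_pred=hr_max_pred)
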