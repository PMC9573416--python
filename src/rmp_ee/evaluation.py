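"""Agreement statistics between estimated and reference energy expenditure.

Covers the coefficient of determination (R^2 = 1 - SS_res/SS_tot), RMSE,
Bland-Altman bias and 95 % limits of agreement, per-intensity paired
comparisons (Kolmogorov-Smirnov normality check on the differences, log
transform on failure, paired t-test with significance tiers), and two
bookkeeping helpers: the window sample-size formula n = z^2 p(1-p)/m^2 and
the windows-per-subject count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvalReport",
    "BlandAltmanResult",
    "r_squared",
    "rmse",
    "bland_altman",
    "per_intensity_comparison",
    "required_windows",
    "bookkeep_windows",
]

logger = logging.getLogger(__name__)

SIGNIFICANCE_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _tier(p: float) -> str:
    for cut, mark in SIGNIFICANCE_TIERS:
        if p < cut:
            return mark
    return "NS"


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float  # mean(pred - ref)
    sd_diff: float
    loa_low: float
    loa_high: float
    frac_within: float
    multiplier: float = 1.96


@dataclass
class EvalReport:
    r2: float
    rmse: float
    n: int
    target: str  # "ee" or "vo2"
    bland_altman: BlandAltmanResult | None = None
    per_intensity: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {"r2": self.r2, "rmse": self.rmse, "n": self.n,
               "target": self.target}
        if self.bland_altman is not None:
            ba = self.bland_altman
            out["bland_altman"] = {
                "bias": ba.bias, "sd_diff": ba.sd_diff, "loa_low": ba.loa_low,
                "loa_high": ba.loa_high, "frac_within": ba.frac_within,
                "multiplier": ba.multiplier,
            }
        if self.per_intensity is not None:
            out["per_intensity"] = self.per_intensity.to_dict(orient="records")
        return out


def _paired(pred, ref, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ValueError("pred and ref must be 1-D arrays of equal length")
    if len(pred) < min_n:
        raise ValueError(f"need at least {min_n} paired values")
    return pred, ref


def r_squared(pred, ref) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot of pred about ref."""
    pred, ref = _paired(pred, ref, 2)
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("reference series is constant; R^2 undefined")
    ss_res = float(np.sum((ref - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(pred, ref) -> float:
    pred, ref = _paired(pred, ref, 1)
    return float(np.sqrt(np.mean((pred - ref) ** 2)))


def bland_altman(pred, ref, multiplier: float = 1.96) -> BlandAltmanResult:
    """Bias and limits of agreement of pred - ref against the pair means."""
    pred, ref = _paired(pred, ref, 3)
    diff = pred - ref
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    lo = bias - multiplier * sd
    hi = bias + multiplier * sd
    frac = float(np.mean((diff >= lo) & (diff <= hi)))
    return BlandAltmanResult(bias=bias, sd_diff=sd, loa_low=lo, loa_high=hi,
                             frac_within=frac, multiplier=multiplier)


def per_intensity_comparison(pred, ref, labels,
                             alpha_normality: float = 0.05) -> pd.DataFrame:
    """Per-intensity paired comparison table.

    For each intensity label: mean +/- SD of both series, mean difference
    +/- SD, a KS normality check on the (standardized) differences, a
    paired t-test — on log-transformed series when normality fails and all
    values are positive — and a significance tier (NS/*/**/***). Labels
    with fewer than two pairs, and the "unknown" label, are skipped.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    labels = np.asarray(labels)
    if not (len(pred) == len(ref) == len(labels)):
        raise ValueError("pred, ref and labels must have equal length")

    rows = []
    for label in pd.unique(labels):
        if label in (None, "unknown"):
            continue
        m = labels == label
        p, r = pred[m], ref[m]
        if len(p) < 2:
            continue
        diff = p - r
        sd_d = diff.std(ddof=1)
        if sd_d > 0:
            ks_p = stats.kstest((diff - diff.mean()) / sd_d, "norm").pvalue
        else:
            ks_p = 1.0
        normal = ks_p >= alpha_normality
        use_log = not normal
        if use_log and (np.any(p <= 0) or np.any(r <= 0)):
            logger.warning(
                "label %s: non-positive values prevent log transform; "
                "using untransformed paired t-test", label)
            use_log = False
        a, b = (np.log(p), np.log(r)) if use_log else (p, r)
        if np.allclose(a, b):
            t_p = 1.0
        else:
            t_p = float(stats.ttest_rel(a, b).pvalue)
        rows.append({
            "intensity": label, "n": int(m.sum()),
            "mean_ref": float(r.mean()), "sd_ref": float(r.std(ddof=1)),
            "mean_pred": float(p.mean()), "sd_pred": float(p.std(ddof=1)),
            "mean_diff": float(diff.mean()), "sd_diff": float(sd_d),
            "ks_p": float(ks_p), "log_transformed": bool(use_log),
            "p_value": t_p, "significance": _tier(t_p),
        })
    return pd.DataFrame(rows)


def required_windows(z: float = 1.96, p: float = 0.05, m: float = 0.02) -> int:
    """Minimum window count n = ceil(z^2 p (1-p) / m^2)."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if m <= 0.0:
        raise ValueError("margin m must be positive")
    return math.ceil(z ** 2 * p * (1.0 - p) / m ** 2)


def bookkeep_windows(subjects: int, per_subject: int = 120) -> int:
    """Analyzable-window bookkeeping: subjects x windows-per-subject."""
    if subjects < 1:
        raise ValueError("subjects must be >= 1")
    return subjects * per_subject
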