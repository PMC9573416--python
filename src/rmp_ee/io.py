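"""CSV/YAML/JSON round-tripping for breaths, traces and configs."""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rmp_ee.synthetic import BreathSample, RmpTrace, SimulatorConfig, RMP_FS

__all__ = [
    "write_breaths_csv", "read_breaths_csv",
    "write_trace_csv", "read_trace_csv",
    "write_simulator_config", "read_simulator_config",
]

logger = logging.getLogger(__name__)

BREATH_COLUMNS = ["t", "duration", "vo2", "vco2", "ve", "ee", "rer"]
TRACE_COLUMNS = ["t", "rc", "ab", "cw", "sp"]


def _check_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")


def write_breaths_csv(breaths: list[BreathSample], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(b) for b in breaths],
                      columns=BREATH_COLUMNS)
    df.to_csv(path, index=False)


def read_breaths_csv(path: str | Path) -> list[BreathSample]:
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: no breath records", stacklevel=2)
        if len(df.columns) > 1:
            _check_columns(df, BREATH_COLUMNS, path)
        return []
    _check_columns(df, BREATH_COLUMNS, path)
    bad = df[BREATH_COLUMNS].isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    return [BreathSample(**{c: float(row[c]) for c in BREATH_COLUMNS})
            for _, row in df.iterrows()]


def write_trace_csv(trace: RmpTrace, path: str | Path) -> None:
    df = pd.DataFrame({"t": trace.t, "rc": trace.rc, "ab": trace.ab,
                       "cw": trace.cw, "sp": trace.sp})
    df.to_csv(path, index=False, float_format="%.17g")


def read_trace_csv(path: str | Path,
                   gains: tuple[float, float, float, float] | None = None
                   ) -> RmpTrace:
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, TRACE_COLUMNS, path)
    if df.empty:
        warnings.warn(f"{path}: empty trace", stacklevel=2)
    t = df["t"].to_numpy()
    if len(t) > 1:
        dt = np.diff(t)
        if not np.allclose(dt, 1.0 / RMP_FS, atol=1e-6):
            raise ValueError(f"{path}: trace is not uniformly sampled at "
                             f"{RMP_FS:g} Hz")
    if gains is None:
        gains = SimulatorConfig().compartment_gains
    return RmpTrace(fs=RMP_FS, t0=float(t[0]) if len(t) else 0.0,
                    rc=df["rc"].to_numpy(), ab=df["ab"].to_numpy(),
                    cw=df["cw"].to_numpy(), sp=df["sp"].to_numpy(),
                    gains=tuple(gains))


def write_simulator_config(config: SimulatorConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config)))


def read_simulator_config(path: str | Path) -> SimulatorConfig:
    data = yaml.safe_load(Path(path).read_text())
    for key in ("compartment_gains", "compartment_fractions"):
        if key in data:
            data[key] = tuple(data[key])
    return SimulatorConfig(**data)
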