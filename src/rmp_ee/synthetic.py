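"""Synthetic graded-exercise respiratory data.

Generates the four ingredients the downstream pipeline consumes:

* subject profiles for three age groups — adults (A), post-pubertal
  adolescents (PP) and pubertal children (P) — drawn from published cohort
  means/SDs;
* an exercise protocol: six minutes sitting or standing, two minutes of rest
  on the ergometer, then a continuous ramp (20 W/min for children <= 12 y,
  30 W/min otherwise) ridden to a VO2 plateau at VO2max;
* breath-by-breath gas exchange (VO2, VCO2, VE, RER, EE) following a
  piecewise ventilatory-equivalents model that places two detectable
  ventilatory thresholds on the ramp, with EE tied exactly to oxygen uptake
  by EE = VO2 (L/min) x 4.825 kcal/L;
* a 15 Hz four-channel distance trace (rib cage, abdomen, chest wall, spine)
  in which a gain-weighted sum of channel excursions reproduces each
  breath's tidal volume — a four-channel extension of the Konno-Mead
  two-compartment chest-wall model.

All draws are routed through ``numpy.random.default_rng`` so identical seeds
give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GROUP_STATS",
    "SubjectProfile",
    "ProtocolPhase",
    "BreathSample",
    "RmpTrace",
    "SimulatorConfig",
    "simulate_subject",
    "simulate_protocol",
    "simulate_gas_exchange",
    "simulate_rmp",
    "true_threshold_times",
]

KCAL_PER_L_O2 = 4.825  # kcal per litre O2 (EE = VO2[L/min] * 4.825)
RMP_FS = 15.0  # Hz, fixed device sampling rate

# Cohort statistics per group: (mean, sd) for age [y], height [cm],
# body mass [kg], VO2max [L/min]; plus hard physiological age bounds.
GROUP_STATS: dict[str, dict] = {
    "A": {
        "age": (28.11, 2.93), "height": (175.67, 12.98),
        "body_mass": (70.66, 18.51), "vo2max": (3.16, 1.21),
        "age_bounds": (18.0, 45.0),
    },
    "PP": {
        "age": (14.75, 0.71), "height": (172.06, 7.79),
        "body_mass": (56.61, 7.61), "vo2max": (3.29, 0.58),
        "age_bounds": (13.0, 17.99),
    },
    "P": {
        "age": (11.67, 0.52), "height": (152.10, 4.29),
        "body_mass": (41.65, 4.84), "vo2max": (1.99, 0.17),
        "age_bounds": (8.0, 12.0),
    },
}

# Lower physiological truncation bounds shared by all groups.
_MIN_HEIGHT, _MIN_MASS, _MIN_VO2MAX = 120.0, 25.0, 0.8


@dataclass(frozen=True)
class SubjectProfile:
    """One simulated participant."""

    subject_id: str
    group: str  # "A" | "PP" | "P"
    age: float  # years
    height: float  # cm
    body_mass: float  # kg
    bmi: float  # kg/m^2
    vo2max: float  # L/min
    seed: int

    def __post_init__(self) -> None:
        if self.group not in GROUP_STATS:
            raise ValueError(f"unknown group label: {self.group!r}")
        if self.vo2max <= 0:
            raise ValueError("vo2max must be positive")


@dataclass(frozen=True)
class ProtocolPhase:
    label: str  # "sitting" | "standing" | "rest" | "ramp"
    start: float  # s
    end: float  # s
    ramp_rate: float = 0.0  # W/min, 0 for non-ramp phases

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("phase end must exceed start")
        if self.ramp_rate not in (0.0, 20.0, 30.0):
            raise ValueError("ramp_rate must be 0, 20 or 30 W/min")


@dataclass(frozen=True)
class BreathSample:
    """One breath-by-breath indirect-calorimetry record (t = end of breath)."""

    t: float  # s
    duration: float  # s
    vo2: float  # mL/min
    vco2: float  # mL/min
    ve: float  # L/min
    ee: float  # kcal/min
    rer: float  # dimensionless


@dataclass(frozen=True)
class RmpTrace:
    """Uniformly sampled four-channel distance signal (cm) at 15 Hz."""

    fs: float
    t0: float
    rc: np.ndarray
    ab: np.ndarray
    cw: np.ndarray
    sp: np.ndarray
    # Gains (L/cm) actually used for this subject; weighting channel
    # excursions by these recovers tidal volume (Konno-Mead inversion).
    gains: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        n = len(self.rc)
        if not (len(self.ab) == len(self.cw) == len(self.sp) == n):
            raise ValueError("all four channels must have equal length")
        if self.fs != RMP_FS:
            raise ValueError(f"fs must be {RMP_FS} Hz")

    @property
    def n_samples(self) -> int:
        return len(self.rc)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def stack(self) -> np.ndarray:
        """Channel-major (4, n) array ordered rc, ab, cw, sp."""
        return np.stack([self.rc, self.ab, self.cw, self.sp])


@dataclass(frozen=True)
class SimulatorConfig:
    """Tunable physiology of the simulator.

    Units: vo2_rest mL/min/kg; vo2_per_watt mL/min/W; the three
    ``ve_vo2_equiv_*`` values parameterize the VE/VO2 equivalent — a flat
    baseline below the first threshold, then slopes per unit of VO2max
    fraction; compartment gains L/cm; noise_sd_distance cm (additive);
    noise_sd_gas fractional (multiplicative).
    """

    vo2_rest: float = 3.5
    vo2_per_watt: float = 10.3
    ve_vo2_equiv_below_th1: float = 24.0
    ve_vo2_equiv_between: float = 20.0
    ve_vo2_equiv_above_th2: float = 45.0
    eq_co2_slope_above_th2: float = 18.0
    rer_rest: float = 0.85
    vt_fraction_max: float = 0.60  # max tidal volume / vital capacity
    vt_rest_fraction: float = 0.09  # resting tidal volume / vital capacity
    compartment_gains: tuple[float, float, float, float] = (0.40, 0.50, 0.15, 0.10)
    compartment_fractions: tuple[float, float, float, float] = (0.45, 0.45, 0.07, 0.03)
    noise_sd_distance: float = 0.05
    noise_sd_gas: float = 0.03
    th1_frac: float = 0.55
    th2_frac: float = 0.80
    plateau_s: float = 45.0
    posture_factor_standing: float = 1.05
    subject_gain_cv: float = 0.10  # per-subject spread of compartment gains

    def __post_init__(self) -> None:
        if not (0.0 < self.th1_frac < self.th2_frac < 1.0):
            raise ValueError("require 0 < th1_frac < th2_frac < 1")
        if self.compartment_gains[0] + self.compartment_gains[1] <= 0:
            raise ValueError("rib-cage + abdomen gains must be positive")

    def noiseless(self) -> "SimulatorConfig":
        return replace(self, noise_sd_distance=0.0, noise_sd_gas=0.0)


def simulate_subject(group: str, seed: int, sd_scale: float = 1.0) -> SubjectProfile:
    """Draw one subject from the group's anthropometric distribution.

    ``sd_scale`` rescales every SD (0 collapses the draw onto the means).
    Values are redrawn until inside physiological bounds, so the result is
    a truncated normal; deterministic for a given seed.
    """
    if group not in GROUP_STATS:
        raise ValueError(f"unknown group label: {group!r}")
    stats = GROUP_STATS[group]
    rng = np.random.default_rng(seed)

    def draw(key: str, lo: float, hi: float = math.inf) -> float:
        mu, sd = stats[key]
        sd = sd * sd_scale
        if sd == 0.0:
            return float(min(max(mu, lo), hi))
        for _ in range(1000):
            x = rng.normal(mu, sd)
            if lo <= x <= hi:
                return float(x)
        return float(min(max(mu, lo), hi))  # pragma: no cover

    lo_age, hi_age = stats["age_bounds"]
    age = draw("age", lo_age, hi_age)
    height = draw("height", _MIN_HEIGHT)
    body_mass = draw("body_mass", _MIN_MASS)
    vo2max = draw("vo2max", _MIN_VO2MAX)
    bmi = body_mass / (height / 100.0) ** 2
    return SubjectProfile(
        subject_id=f"{group}-{seed}", group=group, age=age, height=height,
        body_mass=body_mass, bmi=bmi, vo2max=vo2max, seed=seed,
    )


def _ramp_duration(profile: SubjectProfile, config: SimulatorConfig,
                   ramp_rate: float) -> float:
    """Seconds of ramp until VO2 demand reaches VO2max, plus the plateau."""
    vo2_rest = config.vo2_rest * profile.body_mass  # mL/min
    vo2max = profile.vo2max * 1000.0
    peak_power = max(vo2max - vo2_rest, 0.0) / config.vo2_per_watt  # W
    t_to_max = peak_power * 60.0 / ramp_rate
    return t_to_max + config.plateau_s


def simulate_protocol(profile: SubjectProfile, posture: str, seed: int,
                      config: SimulatorConfig | None = None) -> list[ProtocolPhase]:
    """Protocol phases: 6 min posture, 2 min rest, ramp to exhaustion.

    Ramp rate is 20 W/min for subjects aged <= 12 y and 30 W/min otherwise;
    the ramp terminates when simulated VO2 plateaus at VO2max.
    """
    if posture not in ("sitting", "standing"):
        raise ValueError(f"posture must be 'sitting' or 'standing', got {posture!r}")
    config = config or SimulatorConfig()
    ramp_rate = 20.0 if profile.age <= 12.0 else 30.0
    ramp_len = _ramp_duration(profile, config, ramp_rate)
    return [
        ProtocolPhase(posture, 0.0, 360.0),
        ProtocolPhase("rest", 360.0, 480.0),
        ProtocolPhase("ramp", 480.0, 480.0 + ramp_len, ramp_rate),
    ]


def _check_phases(phases: list[ProtocolPhase]) -> None:
    for a, b in zip(phases, phases[1:]):
        if not math.isclose(a.end, b.start, abs_tol=1e-9):
            raise ValueError("protocol phases must be contiguous")


def _vo2_demand(t: float, phases: list[ProtocolPhase],
                profile: SubjectProfile, config: SimulatorConfig) -> float:
    """Instantaneous noiseless VO2 target (mL/min) at time t."""
    vo2_rest = config.vo2_rest * profile.body_mass
    vo2max = profile.vo2max * 1000.0
    for ph in phases:
        if ph.start <= t < ph.end or ph is phases[-1] and t >= ph.start:
            if ph.label == "standing":
                return vo2_rest * config.posture_factor_standing
            if ph.label in ("sitting", "rest"):
                return vo2_rest
            power = ph.ramp_rate * (t - ph.start) / 60.0
            return min(vo2_rest + config.vo2_per_watt * power, vo2max)
    return vo2_rest


def _equivalents(frac: float, config: SimulatorConfig) -> tuple[float, float]:
    """Noiseless (VE/VO2, VE/VCO2) at a given VO2max fraction.

    VE/VO2 is flat below the first threshold, then rises, then rises more
    steeply above the second; VE/VCO2 stays flat until the second threshold
    (isocapnic buffering) and only then rises. RER = eq_o2/eq_co2 therefore
    climbs through the ramp and crosses 1.1 between VTh2 and VO2max.
    """
    e0 = config.ve_vo2_equiv_below_th1
    eq_o2 = e0
    if frac > config.th1_frac:
        eq_o2 += config.ve_vo2_equiv_between * (min(frac, config.th2_frac)
                                                - config.th1_frac)
    if frac > config.th2_frac:
        eq_o2 += config.ve_vo2_equiv_above_th2 * (frac - config.th2_frac)
    eq_co2 = e0 / config.rer_rest
    if frac > config.th2_frac:
        eq_co2 += config.eq_co2_slope_above_th2 * (frac - config.th2_frac)
    return eq_o2, eq_co2


def _vital_capacity(profile: SubjectProfile) -> float:
    """Rough height-scaled vital capacity (L)."""
    return 4.8 * (profile.height / 175.0) ** 2.5


def simulate_gas_exchange(profile: SubjectProfile, phases: list[ProtocolPhase],
                          config: SimulatorConfig, seed: int) -> list[BreathSample]:
    """Breath-by-breath gas exchange over the whole protocol.

    Breath durations follow tidal volume: VT grows with ventilation toward
    ``vt_fraction_max`` of vital capacity, and duration = 60*VT/VE, so
    breathing deepens first and then quickens as intensity rises (roughly
    4 s at rest down to ~1.5 s near VO2max). Multiplicative gaussian noise
    (``noise_sd_gas``) perturbs VO2 and VE per breath; EE is always exactly
    VO2(L/min) * 4.825 on the (noisy) VO2, and RER = VCO2/VO2.
    """
    _check_phases(phases)
    rng = np.random.default_rng(seed)
    vo2max = profile.vo2max * 1000.0
    vc = _vital_capacity(profile)
    vt_rest = config.vt_rest_fraction * vc
    vt_max = config.vt_fraction_max * vc
    eq_max, _ = _equivalents(1.0, config)
    ve_max = eq_max * vo2max / 1000.0
    ve_rest = config.ve_vo2_equiv_below_th1 * config.vo2_rest * profile.body_mass / 1000.0

    t_end = phases[-1].end
    breaths: list[BreathSample] = []
    t = 0.0
    while t < t_end:
        # provisional duration from the noiseless state at breath start
        vo2_0 = _vo2_demand(t, phases, profile, config)
        eq_o2_0, _ = _equivalents(vo2_0 / vo2max, config)
        ve_0 = eq_o2_0 * vo2_0 / 1000.0
        span = max(0.70 * ve_max - ve_rest, 1e-6)
        vt = vt_rest + (vt_max - vt_rest) * min(max((ve_0 - ve_rest) / span, 0.0), 1.0)
        duration = 60.0 * vt / ve_0
        duration *= 1.0 + rng.normal(0.0, 0.05)
        duration = float(min(max(duration, 1.3), 5.0))
        t_mid = t + duration / 2.0

        vo2 = _vo2_demand(t_mid, phases, profile, config)
        eq_o2, eq_co2 = _equivalents(vo2 / vo2max, config)
        if config.noise_sd_gas > 0:
            vo2 *= 1.0 + rng.normal(0.0, config.noise_sd_gas)
            vo2 = max(vo2, 1.0)
        ve = eq_o2 * vo2 / 1000.0
        if config.noise_sd_gas > 0:
            ve *= 1.0 + rng.normal(0.0, config.noise_sd_gas)
            ve = max(ve, 0.05)
        vco2 = ve / eq_co2 * 1000.0
        t += duration
        breaths.append(BreathSample(
            t=t, duration=duration, vo2=vo2, vco2=vco2, ve=ve,
            ee=vo2 / 1000.0 * KCAL_PER_L_O2, rer=vco2 / vo2,
        ))
    return breaths


def true_threshold_times(profile: SubjectProfile, phases: list[ProtocolPhase],
                         config: SimulatorConfig) -> tuple[float, float]:
    """Generator ground truth: ramp times where VO2 demand crosses the
    configured threshold fractions of VO2max."""
    ramp = phases[-1]
    if ramp.label != "ramp":
        raise ValueError("last phase must be the ramp")
    vo2_rest = config.vo2_rest * profile.body_mass
    vo2max = profile.vo2max * 1000.0
    rate = config.vo2_per_watt * ramp.ramp_rate / 60.0  # mL/min per s
    t1 = ramp.start + (config.th1_frac * vo2max - vo2_rest) / rate
    t2 = ramp.start + (config.th2_frac * vo2max - vo2_rest) / rate
    return t1, t2


def _subject_kinematics(profile: SubjectProfile, config: SimulatorConfig,
                        seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-subject gains (L/cm), volume fractions and baselines (cm)."""
    rng = np.random.default_rng(seed)
    gains = np.asarray(config.compartment_gains, dtype=float)
    if config.subject_gain_cv > 0:
        gains = gains * (1.0 + rng.normal(0.0, config.subject_gain_cv, 4))
        gains = np.maximum(gains, 0.05)
    fracs = np.asarray(config.compartment_fractions, dtype=float)
    fracs = fracs * (1.0 + rng.normal(0.0, 0.05, 4))
    fracs = np.maximum(fracs, 0.0)
    fracs = fracs / fracs.sum()
    scale = profile.height / 175.0
    base = np.array([25.0, 27.0, 30.0, 32.0]) * scale
    base = base + rng.normal(0.0, 0.5, 4)
    return gains, fracs, base


def simulate_rmp(breaths: list[BreathSample], profile: SubjectProfile,
                 config: SimulatorConfig, seed: int) -> RmpTrace:
    """15 Hz four-channel distance trace consistent with the breath series.

    Each breath contributes a raised-cosine volume excursion of amplitude
    VT = VE * duration / 60 (L); channel k moves by fraction f_k of that
    volume divided by its gain g_k (L/cm), so the gain-weighted sum of
    channel excursions reconstructs VT exactly in the noiseless case.
    """
    if not breaths:
        raise ValueError("breaths must be non-empty")
    times = np.array([b.t for b in breaths])
    if np.any(np.diff(times) <= 0):
        raise ValueError("breath end-times must be strictly increasing")

    gains, fracs, base = _subject_kinematics(profile, config, seed)
    rng = np.random.default_rng(seed + 1)

    t_total = breaths[-1].t
    n = int(round(t_total * RMP_FS))
    t = np.arange(n) / RMP_FS
    volume = np.zeros(n)
    for b in breaths:
        start = b.t - b.duration
        vt = b.ve * b.duration / 60.0
        i0 = max(int(math.ceil(start * RMP_FS - 1e-9)), 0)
        i1 = min(int(math.ceil(b.t * RMP_FS - 1e-9)), n)
        if i1 <= i0:
            continue
        phase = (t[i0:i1] - start) / b.duration
        volume[i0:i1] = vt * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))

    channels = []
    for k in range(4):
        ch = base[k] + fracs[k] * volume / gains[k]
        if config.noise_sd_distance > 0:
            ch = ch + rng.normal(0.0, config.noise_sd_distance, n)
        channels.append(ch)
    return RmpTrace(fs=RMP_FS, t0=0.0, rc=channels[0], ab=channels[1],
                    cw=channels[2], sp=channels[3], gains=tuple(gains))
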