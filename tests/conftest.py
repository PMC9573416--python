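import numpy as np
import pytest

from rmp_ee.preprocessing import Window, WindowSet
from rmp_ee.study import simulate_subject_dataset
from rmp_ee.synthetic import BreathSample, SimulatorConfig


@pytest.fixture(scope="session")
def noiseless_config() -> SimulatorConfig:
    return SimulatorConfig().noiseless()


@pytest.fixture(scope="session")
def default_config() -> SimulatorConfig:
    return SimulatorConfig()


@pytest.fixture(scope="session")
def subject_ds(noiseless_config):
    """One fully simulated noiseless post-pubertal subject."""
    return simulate_subject_dataset("PP", seed=42, sim_config=noiseless_config)


def make_breath(t: float, duration: float, vo2: float = 1000.0,
                rer: float = 0.85, eq_o2: float = 24.0) -> BreathSample:
    ve = eq_o2 * vo2 / 1000.0
    vco2 = rer * vo2
    return BreathSample(t=t, duration=duration, vo2=vo2, vco2=vco2, ve=ve,
                        ee=vo2 / 1000.0 * 4.825, rer=rer)


def make_windows(n: int, seed: int = 0, n_samples: int = 8,
                 subjects: int = 1) -> WindowSet:
    """Small random window set with targets linear in the signal mean."""
    rng = np.random.default_rng(seed)
    windows = []
    for i in range(n):
        sig = rng.normal(0.0, 1.0, (4, n_samples))
        ee = 5.0 + 2.0 * sig.mean() + 0.1 * rng.normal()
        windows.append(Window(start=float(i), signal=sig, target_ee=ee,
                              target_vo2=ee * 3.0,
                              subject_id=f"s{i % subjects}"))
    return WindowSet(windows)
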