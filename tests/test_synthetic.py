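"""Simulator: subject draws, protocol structure, gas exchange, distance traces."""

import numpy as np
import pytest

from rmp_ee.synthetic import (GROUP_STATS, SimulatorConfig, simulate_gas_exchange,
                              simulate_protocol, simulate_rmp, simulate_subject,
                              true_threshold_times)


class TestSimulateSubject:
    def test_zero_variance_returns_group_means(self):
        p = simulate_subject("P", seed=5, sd_scale=0.0)
        assert p.age == pytest.approx(11.67)
        assert p.height == pytest.approx(152.10)
        assert p.body_mass == pytest.approx(41.65)

    def test_bmi_consistent_with_mass_and_height(self):
        for seed in range(5):
            p = simulate_subject("A", seed)
            assert p.bmi == pytest.approx(p.body_mass / (p.height / 100) ** 2,
                                          abs=0.1)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            simulate_subject("X", seed=0)

    def test_age_respects_group_bounds(self):
        for group, (lo, hi) in [("A", (18, 45)), ("PP", (13, 18)), ("P", (8, 12))]:
            ages = [simulate_subject(group, s).age for s in range(50)]
            assert all(lo <= a <= hi for a in ages)

    def test_monte_carlo_mean_matches_cohort(self):
        """Sample mean of age over many draws lies within 3 SE of the
        cohort mean used by the generator."""
        mu, sd = GROUP_STATS["A"]["age"]
        ages = np.array([simulate_subject("A", s).age for s in range(1000)])
        se = sd / np.sqrt(len(ages))
        assert abs(ages.mean() - mu) < 3 * se

    def test_deterministic_given_seed(self):
        assert simulate_subject("PP", 7) == simulate_subject("PP", 7)


class TestSimulateProtocol:
    def test_phase_layout(self):
        p = simulate_subject("A", 1)
        phases = simulate_protocol(p, "sitting", 1)
        assert [ph.label for ph in phases] == ["sitting", "rest", "ramp"]
        assert phases[0].start == 0.0 and phases[0].end == 360.0
        assert phases[1].end == 480.0
        for a, b in zip(phases, phases[1:]):
            assert a.end == b.start

    @pytest.mark.parametrize("group,rate", [("P", 20.0), ("PP", 30.0), ("A", 30.0)])
    def test_ramp_rate_by_age(self, group, rate):
        p = simulate_subject(group, seed=3, sd_scale=0.0)
        phases = simulate_protocol(p, "standing", 3)
        assert phases[-1].ramp_rate == rate

    def test_invalid_posture_rejected(self):
        p = simulate_subject("A", 1)
        with pytest.raises(ValueError, match="posture"):
            simulate_protocol(p, "lying", 1)

    def test_ramp_long_enough_to_reach_vo2max(self, noiseless_config):
        p = simulate_subject("PP", 2)
        phases = simulate_protocol(p, "sitting", 2, noiseless_config)
        breaths = simulate_gas_exchange(p, phases, noiseless_config, 2)
        vo2_peak = max(b.vo2 for b in breaths)
        assert vo2_peak == pytest.approx(p.vo2max * 1000.0, rel=0.01)


class TestGasExchange:
    def test_ee_is_exactly_vo2_times_4825(self, default_config):
        p = simulate_subject("A", 4)
        phases = simulate_protocol(p, "sitting", 4, default_config)
        breaths = simulate_gas_exchange(p, phases, default_config, 4)
        for b in breaths:
            assert b.ee == b.vo2 / 1000.0 * 4.825
            assert b.rer == pytest.approx(b.vco2 / b.vo2)

    def test_resting_ee_near_literature_value(self, noiseless_config):
        """An adult of 70.66 kg at 3.5 mL/min/kg rests near 1.19 kcal/min."""
        p = simulate_subject("A", 0, sd_scale=0.0)
        phases = simulate_protocol(p, "sitting", 0, noiseless_config)
        breaths = simulate_gas_exchange(p, phases, noiseless_config, 0)
        resting = [b.ee for b in breaths if b.t < 360.0]
        assert np.mean(resting) == pytest.approx(0.2473 * 4.825, rel=0.01)

    def test_rer_crosses_1_1_late_in_ramp(self, subject_ds):
        rers = [b.rer for b in subject_ds.breaths]
        assert max(rers) > 1.1
        t_cross = next(b.t for b in subject_ds.breaths if b.rer > 1.1)
        _, t_th2 = true_threshold_times(subject_ds.profile, subject_ds.phases,
                                        SimulatorConfig().noiseless())
        assert t_cross > t_th2 - 30.0

    def test_durations_within_bounds_and_shrink(self, subject_ds):
        br = subject_ds.breaths
        assert all(1.0 <= b.duration <= 10.0 for b in br)
        early = np.mean([b.duration for b in br if b.t < 300])
        late = np.mean([b.duration for b in br if b.t > br[-1].t - 60])
        assert late < early

    def test_invalid_threshold_order_rejected(self):
        with pytest.raises(ValueError, match="th1_frac"):
            SimulatorConfig(th1_frac=0.9, th2_frac=0.8)

    def test_deterministic_given_seed(self, default_config):
        p = simulate_subject("P", 9)
        phases = simulate_protocol(p, "sitting", 9, default_config)
        b1 = simulate_gas_exchange(p, phases, default_config, 9)
        b2 = simulate_gas_exchange(p, phases, default_config, 9)
        assert b1 == b2


class TestSimulateRmp:
    def test_sample_count_is_fs_times_duration(self, subject_ds):
        tr = subject_ds.trace
        assert tr.n_samples == int(round(subject_ds.breaths[-1].t * 15.0))

    def test_gain_weighted_excursions_recover_tidal_volume(self, noiseless_config):
        """Konno-Mead inversion: sum_k g_k * excursion_k == VE*dur/60."""
        from tests.conftest import make_breath

        p = simulate_subject("A", 3)
        # one 2 s breath whose peak falls exactly on the 15 Hz grid
        b = make_breath(t=2.0, duration=2.0, vo2=1500.0)
        trace = simulate_rmp([b], p, noiseless_config, 3)
        vt_expected = b.ve * b.duration / 60.0
        vt = sum(g * (ch.max() - ch.min())
                 for g, ch in zip(trace.gains,
                                  (trace.rc, trace.ab, trace.cw, trace.sp)))
        assert vt == pytest.approx(vt_expected, abs=1e-6)

    def test_excursions_linear_in_ventilation(self, noiseless_config):
        from dataclasses import replace

        from tests.conftest import make_breath

        p = simulate_subject("A", 3)
        b1 = make_breath(t=2.0, duration=2.0, vo2=1000.0)
        b2 = replace(b1, ve=2 * b1.ve)
        t1 = simulate_rmp([b1], p, noiseless_config, 3)
        t2 = simulate_rmp([b2], p, noiseless_config, 3)
        for c1, c2 in zip((t1.rc, t1.ab, t1.cw, t1.sp),
                          (t2.rc, t2.ab, t2.cw, t2.sp)):
            assert np.ptp(c2) == pytest.approx(2 * np.ptp(c1), rel=1e-9)

    def test_whole_protocol_conserves_tidal_volume(self, subject_ds):
        """Per-breath, the gain-weighted channel excursion sum reproduces
        VT over the full noiseless protocol."""
        tr = subject_ds.trace
        sig = tr.stack()
        gains = np.asarray(tr.gains)
        t = tr.t
        errs = []
        for b in subject_ds.breaths:
            m = (t >= b.t - b.duration) & (t < b.t)
            if m.sum() < 10:
                continue
            exc = (sig[:, m].max(axis=1) - sig[:, m].min(axis=1))
            vt_hat = float(gains @ exc)
            vt = b.ve * b.duration / 60.0
            errs.append(abs(vt_hat - vt) / vt)
        # peak sampling at 15 Hz bounds the residual, not the model
        assert np.median(errs) < 0.01

    def test_non_monotone_breaths_rejected(self, noiseless_config):
        from tests.conftest import make_breath

        p = simulate_subject("A", 3)
        bs = [make_breath(3.0, 3.0), make_breath(2.0, 2.0)]
        with pytest.raises(ValueError, match="increasing"):
            simulate_rmp(bs, p, noiseless_config, 3)

    def test_deterministic_given_seed(self, subject_ds, noiseless_config):
        tr2 = simulate_rmp(subject_ds.breaths, subject_ds.profile,
                           noiseless_config, 42)
        assert np.array_equal(subject_ds.trace.stack(), tr2.stack())
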