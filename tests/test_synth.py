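"""Generator properties: determinism, conservation, sensor physics limits."""

import numpy as np
import pytest

from insolegrf import (
    GaitConfig,
    SensorParams,
    SiteWeights,
    detect_heel_strikes,
    distribute_load,
    generate_cyclic_test,
    generate_grf,
    generate_session,
    generate_trial,
    sensor_forward,
    voltage_to_resistance,
)
from insolegrf.synth import SITES, _vertical_shape


@pytest.fixture(scope="module")
def short_cfg():
    return GaitConfig(speed_profile=((3.0, 15.0),), sample_rate=100.0)


class TestGenerateGRF:
    def test_swing_vertical_exactly_zero(self, short_cfg):
        grf, events = generate_grf(short_cfg, seed=1)
        v = grf["vertical"]
        assert np.any(v == 0.0)
        # every sample is either in a stance span or exactly zero
        assert np.all((v >= 0.0))

    def test_determinism(self, short_cfg):
        g1, e1 = generate_grf(short_cfg, seed=9)
        g2, e2 = generate_grf(short_cfg, seed=9)
        np.testing.assert_array_equal(e1, e2)
        for a in g1:
            np.testing.assert_array_equal(g1[a], g2[a])
        g3, _ = generate_grf(short_cfg, seed=10)
        assert not np.array_equal(g1["vertical"], g3["vertical"])

    def test_double_bump_vertical(self, short_cfg):
        s = np.linspace(0, 1, 500)
        shape = _vertical_shape(s)
        # local minimum at midstance flanked by two peaks
        mid = shape[240:260].min()
        assert shape[:250].max() > mid and shape[250:].max() > mid
        assert shape.max() == pytest.approx(1.0, abs=1e-3)

    def test_ap_impulse_cancels_per_cycle(self, short_cfg):
        grf, events = generate_grf(short_cfg, seed=4)
        ap = grf["anteroposterior"]
        for a, b in zip(events[:-1], events[1:]):
            cyc = ap[a:b]
            braking = -np.sum(cyc[cyc < 0])
            assert abs(np.sum(cyc)) < 0.02 * braking

    def test_cycle_durations_jittered(self, short_cfg):
        _, events = generate_grf(short_cfg, seed=5)
        durations = np.diff(events)
        assert np.std(durations) > 0


class TestDistributeLoad:
    def test_conservation(self, short_cfg):
        grf, events = generate_grf(short_cfg, seed=2)
        sites = distribute_load(grf["vertical"], events)
        total = sum(sites[s] for s in SITES)
        np.testing.assert_allclose(total, grf["vertical"], atol=1e-9)

    def test_heel_before_toe(self, short_cfg):
        grf, events = generate_grf(short_cfg, seed=2)
        sites = distribute_load(grf["vertical"], events)
        a, b = events[0], events[1]
        hl_peak = a + np.argmax(sites["HL"][a:b])
        to_peak = a + np.argmax(sites["TO"][a:b])
        assert hl_peak < to_peak

    def test_shares_sum_to_one_everywhere(self):
        w = SiteWeights()
        phase = np.linspace(0, 1, 101)
        shares = w.shares(phase)
        np.testing.assert_allclose(sum(shares[s] for s in SITES), 1.0, atol=1e-12)

    def test_uniform_weights_quarter_each(self, short_cfg):
        grf, events = generate_grf(short_cfg, seed=2)
        w = SiteWeights(
            centers={s: 0.5 for s in SITES}, widths={s: 1e6 for s in SITES}, floor=0.0
        )
        sites = distribute_load(grf["vertical"], events, w)
        for s in SITES:
            np.testing.assert_allclose(sites[s], grf["vertical"] / 4.0, atol=1e-9)


class TestSensorForward:
    def _clean_params(self, **kw):
        defaults = dict(noise_sd=0.0, adc_bits=None, drift_magnitude=0.0)
        defaults.update(kw)
        return SensorParams(**defaults)

    def test_zero_force_constant_voltage_at_r0(self):
        p = self._clean_params(lag_tau=0.0)
        v = sensor_forward(np.zeros(100), p, seed=0)
        r = voltage_to_resistance(v)
        np.testing.assert_allclose(r, p.r0, rtol=1e-9)

    def test_step_response_first_order_closed_form(self):
        rate = 100.0
        p = self._clean_params(lag_tau=0.2)
        force = np.full(400, 300.0)
        _, dr = sensor_forward(force, p, rate=rate, seed=0, return_truth=True)
        target = -p.delta_r_max * 300.0 / (300.0 + p.f_half)
        k = np.arange(1, 401, dtype=float)
        expected = target * (1.0 - np.exp(-1.0 / (rate * p.lag_tau)) ** k)
        np.testing.assert_allclose(dr, expected, atol=1e-6 * abs(target))

    def test_saturation_approaches_minus_delta_r_max(self):
        p = self._clean_params(lag_tau=0.0)
        _, dr = sensor_forward(np.full(10, 1e5), p, seed=0, return_truth=True)
        assert dr[-1] == pytest.approx(-90.0, abs=0.2)

    def test_degenerate_limit_is_static_map(self):
        p = self._clean_params(lag_tau=0.0)
        force = np.abs(np.sin(np.linspace(0, 10, 200))) * 400.0
        v, dr = sensor_forward(force, p, seed=0, return_truth=True)
        static = -p.delta_r_max * force / (force + p.f_half)
        np.testing.assert_allclose(dr, static, atol=1e-12)
        r = voltage_to_resistance(v)
        np.testing.assert_allclose(100.0 * (r - p.r0) / p.r0, static, atol=1e-9)

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            sensor_forward(np.array([-1.0]), SensorParams(), seed=0)

    def test_quantization_grid(self):
        p = self._clean_params(lag_tau=0.0, adc_bits=8)
        v = sensor_forward(np.linspace(0, 500, 50), p, seed=0)
        q = 5.0 / 2**8
        np.testing.assert_allclose((v / q - 0.5) % 1.0, 0.0, atol=1e-9)


class TestGenerateTrial:
    def test_default_protocol_five_plateaus(self):
        cfg = GaitConfig()
        assert len(cfg.speed_profile) == 5
        total = sum(d for _, d in cfg.speed_profile)
        assert total == pytest.approx(250.0)

    def test_heel_strike_count_matches_ground_truth(self, short_trial):
        trial, truth = short_trial
        detected = detect_heel_strikes(
            trial.grf["vertical"], trial.body_mass, rate=trial.sample_rate
        )
        assert abs(detected.size - truth["events"].size) <= 1

    def test_determinism(self, short_gait_config):
        t1, _ = generate_trial(short_gait_config, seed=11)
        t2, _ = generate_trial(short_gait_config, seed=11)
        for c in t1.channels:
            np.testing.assert_array_equal(t1.voltages[c], t2.voltages[c])


class TestGenerateSession:
    def test_zero_drift_same_day_statistics(self, short_gait_config):
        from insolegrf.synth import default_sensor_params

        sensors = {
            s: SensorParams(f_half=p.f_half, day_drift_rate=0.0)
            for s, p in default_sensor_params().items()
        }
        session = generate_session(
            days=(0, 7), gait=short_gait_config, sensors=sensors, n_trials=1, seed=5
        )
        v0 = session[0][0][0].voltages["HL"]
        v7 = session[7][0][0].voltages["HL"]
        # distinct noise realizations but identical underlying physics
        assert not np.array_equal(v0, v7)
        assert abs(np.mean(v0) - np.mean(v7)) < 0.05

    def test_day_drift_scales_parameters(self):
        p = SensorParams(day_drift_rate=0.1)
        d7 = p.drifted(7)
        assert d7.f_half == pytest.approx(p.f_half * 1.1**7)
        assert d7.r0 == pytest.approx(p.r0 * 1.1**7)

    def test_distinct_seeds_per_day(self, short_gait_config):
        session = generate_session(days=(0, 1), gait=short_gait_config, n_trials=1, seed=5)
        assert not np.array_equal(
            session[0][0][0].voltages["HL"], session[1][0][0].voltages["HL"]
        )


class TestGenerateCyclicTest:
    def test_peak_force_relaxes_monotonically_to_steady_state(self):
        res = generate_cyclic_test(n_cycles=60, seed=0)
        per = res["period_samples"]
        peaks = res["force"].reshape(60, per).max(axis=1)
        # smooth viscoelastic decay: first peaks highest, tail flat
        assert peaks[0] == peaks.max()
        assert np.all(np.diff(peaks) <= 1e-9)
        assert peaks[-1] == pytest.approx(peaks[-10], rel=1e-3)

    def test_cycle_count_recovered_by_split(self):
        from insolegrf import split_cycles

        res = generate_cyclic_test(n_cycles=100, seed=1)
        loops = split_cycles(res["force"], res["delta_r"], res["period_samples"])
        assert len(loops) == 100

    def test_triangular_displacement_amplitude(self):
        res = generate_cyclic_test(n_cycles=5, displacement_mm=5.0, seed=0)
        # peak may fall between samples: tolerance of one sample step
        step = 2 * 5.0 / res["period_samples"]
        assert res["displacement_mm"].max() == pytest.approx(5.0, abs=step)
        assert res["displacement_mm"].min() == 0.0
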