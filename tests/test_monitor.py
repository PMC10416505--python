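"""Streaming monitor: U grading, step recursion, batch driver, comparisons."""

import math

import numpy as np
import pandas as pd
import pytest

from ulcerguard import (
    ConfigurationError,
    DataError,
    MonitorConfig,
    PressureClass,
    ReliefSpec,
    beta_exponential,
    compare_methods,
    compute_U,
    compute_q_m,
    cscm_config,
    default_damage_limit,
    estimate_q,
    initial_state,
    run,
    standard_method_configs,
    step,
)
from ulcerguard.monitor import TRACE_COLUMNS


def exp_config(relief_time_s=300.0, **kw):
    return MonitorConfig(relief=ReliefSpec("exponential", relief_time_s=relief_time_s), **kw)


def lin_config(relief_time_s=300.0, **kw):
    return MonitorConfig(relief=ReliefSpec("linear", relief_time_s=relief_time_s), **kw)


class TestComputeU:
    q_m = compute_q_m(0.1)

    def test_complete_relief(self):
        assert compute_U([0.0, 0.0, 0.0], self.q_m) == 0.0

    def test_clamped_at_one_under_damaging_load(self):
        assert compute_U([2 * self.q_m], self.q_m) == 1.0
        assert compute_U([self.q_m], self.q_m) == 1.0

    def test_graded_relief(self):
        assert compute_U([0.25 * self.q_m], self.q_m) == pytest.approx(0.25)

    def test_invalid_normaliser_or_empty_buffer(self):
        with pytest.raises(ConfigurationError):
            compute_U([0.1], 0.0)
        with pytest.raises(ConfigurationError):
            compute_U([], self.q_m)


class TestStep:
    def test_zero_pressure_stream_stays_at_zero(self):
        cfg = exp_config()
        state = initial_state(cfg)
        for _ in range(100):
            state, out = step(state, 0.0, cfg)
            assert out.I == 0.0 and out.q == 0.0 and out.U == 0.0
            assert not out.redistribution_alarm and not out.relief_alarm

    def test_sustained_damaging_load_is_pure_integration(self):
        # q >= q_m every step, so U = 1 and no decay applies: I = n * q_step
        cfg = exp_config()
        q_step = estimate_q(cfg.dt_s / 60.0, 20.0)
        state = initial_state(cfg)
        expected = 0.0
        for _ in range(500):
            state, out = step(state, 20.0, cfg)
            expected += q_step
            assert out.I == expected
            assert out.U == 1.0

    def test_impulse_decays_exponentially_to_harmless_fraction(self):
        cfg = exp_config(relief_time_s=300.0)
        beta = beta_exponential(cfg.dt_s, 300.0)
        state = initial_state(cfg)
        state, out = step(state, 20.0, cfg)
        peak = out.I
        assert peak == estimate_q(cfg.dt_s / 60.0, 20.0)
        n_relief = round(300.0 / cfg.dt_s)
        for _ in range(n_relief):
            state, out = step(state, 0.0, cfg)
        assert out.I / peak == pytest.approx(math.exp(-5.0), rel=1e-9)

    def test_linear_mode_clamps_at_zero_during_relief(self):
        cfg = lin_config(relief_time_s=1.0)  # beta = 0.1: fast decay
        state = initial_state(cfg)
        state, out = step(state, 15.0, cfg)
        for _ in range(20):
            state, out = step(state, 0.0, cfg)
            assert out.I >= 0.0
        assert out.I == 0.0

    def test_invalid_pressure_names_sample_index(self):
        cfg = exp_config()
        state = initial_state(cfg)
        state, _ = step(state, 10.0, cfg)
        with pytest.raises(DataError, match="index 1"):
            step(state, float("nan"), cfg)
        with pytest.raises(DataError, match="index 1"):
            step(state, -3.0, cfg)

    def test_redistribution_alarm_iff_instantaneously_damaging(self):
        cfg = exp_config()
        state = initial_state(cfg)
        for p, expected in [(8.0, False), (20.0, False), (32.0, True), (40.0, True), (5.0, False)]:
            state, out = step(state, p, cfg)
            assert out.redistribution_alarm is expected
            assert out.redistribution_alarm == (
                out.pressure_class is PressureClass.INSTANTANEOUSLY_DAMAGING
            )


class TestRun:
    def test_empty_signal_gives_empty_trace_with_columns(self):
        trace = run([], exp_config())
        assert len(trace) == 0
        assert list(trace.columns) == TRACE_COLUMNS

    def test_run_equals_sequential_fold_of_step(self):
        rng = np.random.default_rng(4)
        pressures = rng.uniform(0, 40, 300)
        cfg = exp_config()
        trace = run(pressures, cfg)
        state = initial_state(cfg)
        for k, p in enumerate(pressures):
            state, out = step(state, p, cfg)
            assert trace["I"].iloc[k] == out.I
            assert trace["q"].iloc[k] == out.q
            assert trace["U"].iloc[k] == out.U
            assert trace["pressure_class"].iloc[k] == out.pressure_class.value
            assert bool(trace["relief_alarm"].iloc[k]) == out.relief_alarm

    def test_constant_accumulating_load_grows_monotonically(self):
        trace = run(np.full(1000, 10.0), exp_config())
        assert (trace["pressure_class"] == "accumulating").all()
        assert (np.diff(trace["I"]) > 0).all()

    def test_nonuniform_timestamps_rejected_with_index(self):
        sig = pd.DataFrame({"time_s": [0.0, 0.1, 0.25, 0.3], "pressure_kpa": [1.0] * 4})
        with pytest.raises(DataError, match="index 2"):
            run(sig, exp_config())

    def test_relief_alarm_first_crossing_matches_brute_force_scan(self):
        cfg = exp_config(damaging_effect_limit=50.0)
        trace = run(np.full(200, 20.0), cfg)
        alarms = trace["relief_alarm"].to_numpy()
        first = int(np.argmax(alarms))
        assert alarms[first]
        # brute force: no alarm before the first I >= limit, alarm ever after under load
        crossings = np.nonzero(trace["I"].to_numpy() >= 50.0)[0]
        assert first == crossings[0]
        assert not alarms[:first].any()
        assert alarms[first:].all()


class TestCompareMethods:
    def test_all_zero_input_all_methods_zero(self):
        configs = standard_method_configs(dt_s=0.1, window_len=10)
        table = compare_methods(np.zeros(50), configs)
        assert set(table["method"]) == set(configs)
        assert (table["I"] == 0.0).all()

    def test_integrator_methods_agree_exactly_under_sustained_load(self):
        configs = standard_method_configs(dt_s=0.1, window_len=20)
        table = compare_methods(np.full(400, 20.0), configs)
        wide = table.pivot(index="sample", columns="method", values="I")
        for m in ("fixed", "inverse", "linear", "exponential"):
            assert (wide[m] == wide["linear"]).all(), m
        # averaging plateaus at q_step after one window; integrators keep growing
        assert wide["averaging"].iloc[-1] == pytest.approx(wide["averaging"].iloc[25])
        assert wide["linear"].iloc[-1] > wide["linear"].iloc[25]

    def test_impulse_responses_have_method_specific_shapes(self):
        w = 10
        configs = standard_method_configs(dt_s=0.1, relief_time_s=5.0,
                                          fixed_relief_time_s=2.0, window_len=w)
        pressures = np.zeros(200)
        pressures[0] = 20.0
        table = compare_methods(pressures, configs)
        wide = table.pivot(index="sample", columns="method", values="I")
        # averaging: boxcar of width w, then exact zero
        assert (wide["averaging"].iloc[:w] == wide["averaging"].iloc[0]).all()
        assert (wide["averaging"].iloc[w:] == 0.0).all()
        # fixed: held until 2 s of continuous relief (20 samples), then zero
        assert (wide["fixed"].iloc[:20] == wide["fixed"].iloc[0]).all()
        assert (wide["fixed"].iloc[21:] == 0.0).all()
        # inverse: hyperbolic decay, never increasing
        assert (np.diff(wide["inverse"]) <= 0).all()
        # linear: exact zero at t_r (5 s = 50 samples after the impulse)
        assert wide["linear"].iloc[55] == 0.0
        # exponential: e^-5 of the peak at t_r
        assert wide["exponential"].iloc[50] / wide["exponential"].iloc[0] == pytest.approx(
            math.exp(-5.0), rel=1e-6
        )

    def test_mismatched_dt_rejected(self):
        configs = standard_method_configs(dt_s=0.1)
        bad = {"exponential": MonitorConfig(dt_s=0.2, relief=ReliefSpec("exponential")),
               "linear": configs["linear"]}
        with pytest.raises(ConfigurationError, match="dt_s"):
            compare_methods(np.zeros(5), bad)


class TestLimitsAndGuidelineConfig:
    def test_default_limit_is_15_minutes_of_midpoint_load(self):
        cfg = exp_config()
        q_mid = estimate_q(cfg.dt_s / 60.0, 9.0 + 23.0 / 2.0)
        assert default_damage_limit(cfg) == pytest.approx(9000 * q_mid)

    def test_cscm_constant_load_alarms_at_fifteen_minutes(self):
        cfg = cscm_config(dt_s=0.1, pressure_kpa=10.0)
        n = round(15 * 60 / cfg.dt_s)
        trace = run(np.full(n + 100, 10.0), cfg)
        first = int(np.argmax(trace["relief_alarm"].to_numpy()))
        assert abs(first - (n - 1)) <= 1  # 15 min +- one sample (0-indexed)
        assert trace["relief_alarm"].to_numpy()[first]

    def test_nondamaging_guideline_pressure_rejected(self):
        with pytest.raises(Exception, match="non-damaging"):
            cscm_config(pressure_kpa=5.0)
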