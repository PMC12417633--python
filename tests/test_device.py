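"""Device model: pulse response, multilevel programming, switching, energy."""

import math

import numpy as np
import pytest

from fibrc.device import (ConfigurationError, DeviceParams, DeviceState,
                          Pulse, PulseTrain, apply_pulse,
                          count_distinct_levels, energy_of_train, iv_sweep,
                          program_levels, program_states, read_current,
                          reset_to_baseline)


def scalar_recurrence(amps, gaps, p: DeviceParams) -> float:
    """Independent straight-line oracle for the noiseless state update."""
    w = p.w_min
    for a, g in zip(amps, gaps):
        if a >= p.v_set:
            w = w + p.a_write * (p.w_max - w)
        elif a <= p.v_reset:
            w = p.w_min
        w = p.w_min + (w - p.w_min) * math.exp(-g / p.tau_decay)
    return w


class TestParamsAndReset:
    def test_baseline_state(self, params):
        s = reset_to_baseline(params)
        assert s.w == params.w_min and s.t == 0.0
        assert read_current(s, params) == params.i_off

    def test_reset_determinism(self):
        p = DeviceParams(sigma_c2c=0.05, seed=42)
        s1, s2 = reset_to_baseline(p), reset_to_baseline(p)
        assert (s1.w, s1.t) == (s2.w, s2.t)
        pulse = Pulse(p.v_write, 0.2, 0.05)
        t1 = [apply_pulse(s1, pulse, p).w for _ in range(3)]
        # same seeds give byte-identical noisy trajectories
        a, b = reset_to_baseline(p), reset_to_baseline(p)
        for _ in range(5):
            a = apply_pulse(a, pulse, p)
            b = apply_pulse(b, pulse, p)
            assert a.w == b.w

    @pytest.mark.parametrize("bad", [
        {"a_write": 0.0}, {"a_write": 1.0}, {"tau_decay": -1.0},
        {"i_off": 2e-9}, {"v_set": -0.5}, {"v_reset": 0.5},
        {"sigma_c2c": -0.1}, {"tau_decay": float("nan")},
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            DeviceParams(**bad)


class TestApplyPulse:
    def test_pure_exponential_decay(self, params):
        s = DeviceState(w=0.8)
        out = apply_pulse(s, Pulse(0.0, 0.2, 3 * params.tau_decay), params)
        assert out.w == pytest.approx(0.8 * math.exp(-3), rel=1e-12)

    def test_single_write_from_baseline(self, params):
        s = reset_to_baseline(params)
        out = apply_pulse(s, Pulse(params.v_write, 0.2, 0.0), params)
        assert out.w == pytest.approx(params.a_write, abs=0)

    def test_reset_pulse_ruptures_filament(self, params):
        s = DeviceState(w=0.9)
        out = apply_pulse(s, Pulse(params.v_reset - 0.5, 0.2, 0.0), params)
        assert out.w == params.w_min

    def test_clock_monotone_and_advances(self, params):
        s = reset_to_baseline(params)
        out = apply_pulse(s, Pulse(0.0, 0.2, 0.05), params)
        assert out.t == pytest.approx(0.25)

    def test_composition_matches_scalar_oracle(self, params):
        bits = [1, 0, 1, 1]
        amps = [params.v_write if b else 0.0 for b in bits]
        gaps = [0.05] * 4
        s = reset_to_baseline(params)
        for a, g in zip(amps, gaps):
            s = apply_pulse(s, Pulse(a, 0.2, g), params)
        assert s.w == pytest.approx(scalar_recurrence(amps, gaps, params),
                                    rel=1e-12)

    def test_random_trains_match_oracle(self, params, rng):
        for _ in range(50):
            n = rng.integers(1, 30)
            amps = rng.choice([-1.5, 0.0, 0.7, 1.5], size=n)
            gaps = rng.uniform(0.0, 1.0, size=n)
            s = reset_to_baseline(params)
            for a, g in zip(amps, gaps):
                s = apply_pulse(s, Pulse(float(a), 0.2, float(g)), params)
            expect = scalar_recurrence(amps, gaps, params)
            assert s.w == pytest.approx(expect, rel=1e-12, abs=1e-15)


class TestReadCurrent:
    def test_endpoints(self, params):
        assert read_current(DeviceState(w=params.w_min), params) == params.i_off
        assert read_current(DeviceState(w=params.w_max), params) == params.i_on

    def test_linear_midpoint(self):
        p = DeviceParams(p_nl=1.0)
        mid = read_current(DeviceState(w=0.5), p)
        assert mid == pytest.approx((p.i_off + p.i_on) / 2, rel=1e-12)

    def test_strictly_increasing(self, params):
        ws = np.linspace(0, 1, 100)
        cur = [read_current(DeviceState(w=w), params) for w in ws]
        assert np.all(np.diff(cur) > 0)

    def test_non_destructive(self, params):
        s = DeviceState(w=0.4, t=1.0)
        read_current(s, params)
        assert (s.w, s.t) == (0.4, 1.0)


class TestProgramStates:
    def test_empty_frame_reads_off_current(self, params):
        assert program_states("0000", params) == params.i_off

    def test_fading_memory_single_pulse(self, params):
        assert program_states("0001", params) > program_states("1000", params)

    def test_sixteen_distinct_levels(self, params):
        levels = program_levels(params, frame_k=4)
        assert len(levels) == 16
        assert count_distinct_levels(list(levels.values())) == 16

    def test_non_binary_frame_rejected(self, params):
        with pytest.raises(ValueError):
            program_states([0, 2, 1, 0], params)


class TestIVSweep:
    def test_pinched_at_origin(self, params):
        sweep = iv_sweep(params, v_max=1.5)
        zero_v = sweep[sweep[:, 0] == 0.0]
        assert zero_v.shape[0] >= 3
        assert np.all(zero_v[:, 1] == 0.0)

    def test_on_off_ratio(self, params):
        n = 301
        sweep = iv_sweep(params, v_max=1.5, n_points=n)
        fwd = sweep[:n]
        ret = sweep[n - 1:2 * n - 1]
        # OFF conductance from the forward branch below v_set, ON from the
        # return branch; their ratio at v_read is i_on/i_off by construction
        off_pts = fwd[(fwd[:, 0] > 0) & (fwd[:, 0] < params.v_set)]
        on_pts = ret[ret[:, 0] > 0]
        g_off = off_pts[-1, 1] / off_pts[-1, 0]
        g_on = on_pts[0, 1] / on_pts[0, 0]
        assert g_on / g_off == pytest.approx(params.i_on / params.i_off,
                                             rel=1e-6)

    def test_set_at_threshold_sample(self, params):
        sweep = iv_sweep(params, v_max=1.5, n_points=151)
        v, i = sweep[:151, 0], sweep[:151, 1]
        g_on = params.i_on / params.v_read
        switched = i >= g_on * v - 1e-18
        first = np.argmax(switched & (v > 0))
        assert v[first] >= params.v_set
        assert v[first - 1] < params.v_set

    def test_hysteresis_between_set_and_vmax(self, params):
        n = 151
        sweep = iv_sweep(params, v_max=1.5, n_points=n)
        fwd = sweep[:n]
        ret = sweep[n - 1:2 * n - 1][::-1]
        sel = (fwd[:, 0] > 0.2) & (fwd[:, 0] < params.v_set)
        assert np.all(ret[sel, 1] > fwd[sel, 1])

    def test_subthreshold_sweep_rejected(self, params):
        with pytest.raises(ConfigurationError):
            iv_sweep(params, v_max=0.5)


class TestEnergy:
    def test_zero_train(self, params):
        train = PulseTrain([Pulse(0.0, 0.2, 0.05)] * 8)
        e, pwr = energy_of_train(train, params)
        assert e == 0.0 and pwr == 0.0

    def test_read_power_sub_nanowatt(self, params):
        train = PulseTrain([Pulse(params.v_read, 0.2, 0.0)])
        _, pwr = energy_of_train(
            train, params, state=DeviceState(w=params.w_max))
        assert pwr < 1e-9

    def test_matches_dense_integration(self, params, rng):
        pulses = [Pulse(float(rng.choice([0.0, 1.5])), 0.2, 0.05)
                  for _ in range(12)]
        e, _ = energy_of_train(PulseTrain(pulses), params)
        # oracle: trapezoidal integration of V(t)*I(t) on a dense grid
        dt = 1e-4
        s = reset_to_baseline(params)
        t_edges, vs, cs = [], [], []
        for p in pulses:
            i_now = read_current(s, params)
            n = int(round(p.duration / dt))
            vs.extend([p.amplitude] * n)
            cs.extend([i_now] * n)
            m = int(round(p.gap_after / dt))
            vs.extend([0.0] * m)
            cs.extend([0.0] * m)
            s = apply_pulse(s, p, params)
        power = np.abs(np.asarray(vs) * np.asarray(cs))
        e_oracle = float(np.trapezoid(power, dx=dt))
        assert e == pytest.approx(e_oracle, rel=0.01)


class TestStatePropertyBased:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.tuples(
        st.sampled_from([-1.5, 0.0, 0.8, 1.0, 1.5]),
        st.floats(0.0, 2.0, allow_nan=False)), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_state_stays_in_bounds_and_matches_oracle(self, train):
        p = DeviceParams()
        s = reset_to_baseline(p)
        for a, g in train:
            s = apply_pulse(s, Pulse(a, 0.2, g), p)
            assert p.w_min <= s.w <= p.w_max
        amps, gaps = zip(*train)
        assert s.w == pytest.approx(scalar_recurrence(amps, gaps, p),
                                    rel=1e-12, abs=1e-15)


class TestDynamicalProperties:
    def test_fading_memory_monotone_in_age(self, params):
        # a lone write pulse contributes less the longer ago it occurred
        frames = ["10000000", "01000000", "00100000", "00010000",
                  "00001000", "00000100", "00000010", "00000001"]
        cur = [program_states(f, params) for f in frames]
        assert np.all(np.diff(cur) > 0)

    def test_echo_state_convergence(self, params):
        train = [Pulse(params.v_write, 0.2, 0.05)] * 10 \
            + [Pulse(0.0, 0.2, 0.05)] * 9 \
            + [Pulse(0.0, 0.2, 5 * params.tau_decay)]
        a = DeviceState(w=params.w_min)
        b = DeviceState(w=params.w_max)
        for p in train:
            a = apply_pulse(a, p, params)
            b = apply_pulse(b, p, params)
        assert abs(a.w - b.w) < 1e-3

    def test_injectivity_margin(self, params):
        vals = np.sort(list(program_levels(params, 4).values()))
        margins = np.diff(vals) / vals[1:]
        assert margins.min() >= 0.01

    def test_noisy_trajectories_reproducible(self):
        p = DeviceParams(sigma_c2c=0.1, seed=9)
        frames = "1101"
        assert program_states(frames, p) == program_states(frames, p)

    def test_noise_perturbs_levels(self):
        clean = program_states("1101", DeviceParams())
        noisy = program_states("1101", DeviceParams(sigma_c2c=0.2, seed=3))
        assert noisy != clean
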