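"""Filter response, burst phases, order parameter and dose metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stngpe import (FilterState, filter_step, filter_propagator, compute_lfp,
                    detect_burst_onsets, neuron_phase, phase_trace,
                    order_parameter, order_parameter_trace, mean_peak_period,
                    stimulation_time_fraction, administered_stimulation)


class TestFilter:
    def _run(self, inp, dt, state=None):
        st_ = state or FilterState()
        out = np.empty(inp.size)
        for i, val in enumerate(inp):
            st_ = filter_step(st_, val, dt)
            out[i] = st_.x
        return out

    def test_energy_decays_without_input(self):
        st_ = FilterState(u=1.0, udot=0.5)
        w = st_.omega
        energies = []
        for _ in range(5):
            for _ in range(200):
                st_ = filter_step(st_, 0.0, st_.period / 200)
            energies.append(w ** 2 * st_.u ** 2 + st_.udot ** 2)
        assert all(e2 < e1 for e1, e2 in zip(energies, energies[1:]))

    def test_unit_gain_zero_phase_at_resonance(self):
        """With k_f = alpha_d the steady-state response to a resonant
        sinusoid has unit amplitude and zero phase shift."""
        st_ = FilterState()
        w = st_.omega
        dt = 0.5
        t = np.arange(0.0, 40 * st_.period, dt)
        inp = 0.02 * np.sin(w * t)
        out = self._run(inp, dt)
        tail = slice(int(0.8 * t.size), None)
        amp_ratio = out[tail].max() / 0.02
        assert amp_ratio == pytest.approx(1.0, abs=0.03)
        # zero phase shift: input and output maxima coincide
        corr = np.corrcoef(inp[tail], out[tail])[0, 1]
        assert corr > 0.999

    def test_linearity(self):
        dt = 1.0
        rng = np.random.default_rng(0)
        a = rng.standard_normal(400) * 0.01
        b = rng.standard_normal(400) * 0.01
        out_sum = self._run(a + b, dt)
        np.testing.assert_allclose(out_sum, self._run(a, dt) + self._run(b, dt),
                                   atol=1e-15)

    def test_propagator_matches_reference_solver(self):
        """Exact one-step propagator agrees with a high-accuracy adaptive
        integration of the oscillator ODE under constant input."""
        from scipy.integrate import solve_ivp

        alpha, kf, w, dt = 0.008, 0.008, 2 * np.pi / 103.0, 0.5
        E, f = filter_propagator(alpha, kf, w, dt)
        sol = solve_ivp(lambda t, y: [y[1], -alpha * y[1] - w * w * y[0] + kf * 0.05],
                        (0.0, dt), [0.2, -0.1], rtol=1e-12, atol=1e-14)
        coarse = E @ np.array([0.2, -0.1]) + f * 0.05
        assert coarse[0] == pytest.approx(sol.y[0, -1], rel=1e-9)
        assert coarse[1] == pytest.approx(sol.y[1, -1], rel=1e-9)


class TestLfpAndPhases:
    def test_lfp_is_mean(self, rng):
        s = rng.uniform(0, 1, 37)
        assert compute_lfp(s) == pytest.approx(s.sum() / 37)
        with pytest.raises(ValueError):
            compute_lfp(np.array([]))

    def test_burst_onsets_grouping(self):
        onsets = detect_burst_onsets([0.0, 3.0, 6.0, 103.0, 106.0], isi_gap=25.0)
        np.testing.assert_allclose(onsets, [0.0, 103.0])
        assert detect_burst_onsets([5.0]).tolist() == [5.0]
        assert detect_burst_onsets([]).size == 0
        with pytest.raises(ValueError):
            detect_burst_onsets([5.0, 1.0])

    def test_phase_interpolation(self):
        onsets = [0.0, 100.0, 220.0]
        assert neuron_phase(onsets, 0.0) == pytest.approx(0.0)
        assert neuron_phase(onsets, 100.0) == pytest.approx(2 * np.pi)
        assert neuron_phase(onsets, 50.0) == pytest.approx(np.pi)
        assert neuron_phase(onsets, 160.0) == pytest.approx(3 * np.pi)
        with pytest.raises(ValueError):
            neuron_phase(onsets, 221.0)

    def test_phase_trace_matches_scalar(self):
        onsets = [0.0, 80.0, 200.0, 310.0]
        times = np.linspace(0.0, 310.0, 64)
        psi, valid = phase_trace(onsets, times)
        assert valid.all()
        for t, p in zip(times, psi):
            assert p == pytest.approx(neuron_phase(onsets, t))

    def test_order_parameter_extremes(self):
        assert order_parameter(np.full(50, 1.3)) == pytest.approx(1.0)
        roots = 2 * np.pi * np.arange(8) / 8
        assert order_parameter(roots) == pytest.approx(0.0, abs=1e-12)

    def test_order_parameter_uniform_random_level(self, rng):
        """E[R] for N uniform phases ~ sqrt(pi/(4N)) (Rayleigh)."""
        N = 200
        vals = [order_parameter(rng.uniform(0, 2 * np.pi, N))
                for _ in range(400)]
        expect = np.sqrt(np.pi / (4 * N))
        assert np.mean(vals) == pytest.approx(expect, rel=0.1)

    @given(shift=st.floats(-10, 10))
    @settings(max_examples=25, deadline=None)
    def test_order_parameter_invariant_under_global_shift(self, shift):
        rng = np.random.default_rng(3)
        phases = rng.uniform(0, 2 * np.pi, 40)
        assert order_parameter(phases + shift) == pytest.approx(
            order_parameter(phases), abs=1e-12)

    def test_trace_excludes_undefined_neurons(self):
        lists = [np.array([0.0, 100.0]), np.array([50.0, 150.0])]
        R = order_parameter_trace(lists, np.array([25.0, 75.0, 125.0, 175.0]))
        # t=25: only neuron 0 defined -> R = 1; t=175: nobody -> NaN
        assert R[0] == pytest.approx(1.0)
        assert np.isfinite(R[1]) and np.isfinite(R[2])
        assert np.isnan(R[3])

    def test_mean_peak_period_of_sine(self):
        dt = 0.5
        t = np.arange(0.0, 3000.0, dt)
        period = mean_peak_period(np.sin(2 * np.pi * t / 103.0), dt)
        assert period == pytest.approx(103.0, abs=dt)


class TestDoseMetrics:
    def test_fraction_and_average(self, rng):
        gate = (rng.uniform(size=1000) < 0.3).astype(np.uint8)
        assert stimulation_time_fraction(gate) == pytest.approx(gate.sum() / 1000)
        assert stimulation_time_fraction(np.ones(10)) == 1.0
        with pytest.raises(ValueError):
            stimulation_time_fraction(np.ones(0))

    def test_adbs_identity(self):
        """For on-off gated constant intensity, <|S|> = K * T_on exactly."""
        rng = np.random.default_rng(7)
        gate = (rng.uniform(size=5000) < 0.4).astype(np.uint8)
        K = 1.7
        S = K * gate
        assert administered_stimulation(S) == K * stimulation_time_fraction(gate)

    def test_mean_absolute_sine(self):
        t = np.linspace(0.0, 2 * np.pi * 50, 500_000)
        S = 0.3 * np.sin(t)
        assert administered_stimulation(S) == pytest.approx(2 * 0.3 / np.pi,
                                                            rel=1e-3)
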