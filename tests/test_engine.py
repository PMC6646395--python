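"""Closed-loop engine: determinism, stimulation-mode limits, convergence and
equivalence to the single-cell reference at zero coupling."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from stngpe import (ControllerConfig, NetworkConfig, PulseTrainConfig,
                    SimulationConfig, STN_PARAMS, cell_rhs, NeuronState,
                    integrate, run_protocol, sweep)


def _cfg(net=None, ctl=None, pulse=None, **kw):
    base = dict(duration_ms=1500.0, stim_onset_ms=500.0,
                transient_skip_ms=300.0, ic_seed=7)
    base.update(kw)
    return SimulationConfig(network=net or NetworkConfig(N=20, seed=42),
                            controller=ctl or ControllerConfig(mode="cDBS", K=0.0),
                            pulse=pulse or PulseTrainConfig(), **base)


class TestDeterminismAndLimits:
    def test_same_seed_bitwise_identical(self):
        r1 = integrate(_cfg(ctl=ControllerConfig(mode="aDBS", K=1.0,
                                                 Th_on=0.01, Th_off=0.005)))
        r2 = integrate(_cfg(ctl=ControllerConfig(mode="aDBS", K=1.0,
                                                 Th_on=0.01, Th_off=0.005)))
        assert np.array_equal(r1.lfp, r2.lfp)
        assert np.array_equal(r1.spike_times, r2.spike_times)
        assert r1.summary == r2.summary

    @pytest.mark.parametrize("mode", ["cDBS", "aDBS", "cpLDF", "apLDF"])
    def test_zero_intensity_equals_stim_free(self, mode):
        """With K = 0 every mode leaves the trajectory identical to the
        stimulation-free run under the same seed."""
        kw = dict(Th_on=0.01, Th_off=0.005) if mode in ("aDBS", "apLDF") else {}
        if mode in ("cpLDF", "apLDF"):
            kw["tau"] = 20.0
        ref = integrate(_cfg())
        res = integrate(_cfg(ctl=ControllerConfig(mode=mode, K=0.0, **kw)))
        np.testing.assert_array_equal(res.lfp, ref.lfp)
        np.testing.assert_array_equal(res.spike_times, ref.spike_times)

    def test_adaptive_reduces_to_continuous_at_minus_inf_thresholds(self):
        """aDBS with thresholds at -inf reproduces cDBS sample-for-sample
        (T_on = 1 over the stimulated window)."""
        cont = integrate(_cfg(ctl=ControllerConfig(mode="cDBS", K=0.8)))
        adap = integrate(_cfg(ctl=ControllerConfig(mode="aDBS", K=0.8)))
        # thresholds at -inf: the gate stays on from the onset onward
        on = slice(int(500 / 0.05) + 1, None)
        np.testing.assert_array_equal(adap.gate[on], 1)
        np.testing.assert_array_equal(adap.lfp, cont.lfp)
        assert adap.summary["T_on"] == 1.0

    def test_cdbs_amplitude_constant_after_ramp(self):
        res = integrate(_cfg(ctl=ControllerConfig(mode="cDBS", K=1.5,
                                                  T_ramp=200.0)))
        t = np.arange(res.A.size) * 0.05
        after = res.A[(t > 800.0)]
        assert np.all(after == 1.5)

    def test_adbs_dose_identity(self):
        """<|S|> = K * T_on to machine precision for on-off gated aDBS."""
        res = integrate(_cfg(ctl=ControllerConfig(mode="aDBS", K=1.3,
                                                  Th_on=0.012, Th_off=0.006),
                             duration_ms=3000.0))
        assert res.summary["S_abs_mean"] == pytest.approx(
            1.3 * res.summary["T_on"], abs=1e-12)

    def test_ldf_zero_delay_silent(self):
        res = integrate(_cfg(ctl=ControllerConfig(mode="cpLDF", K=5.0, tau=0.0)))
        assert np.all(res.S == 0.0)
        assert res.summary["S_abs_mean"] == 0.0

    def test_blowup_detected(self):
        bad_net = NetworkConfig(N=20, seed=42, stn_iapp_mean=1e8)
        with pytest.raises(FloatingPointError):
            integrate(_cfg(net=bad_net, duration_ms=200.0))


class TestNumerics:
    def test_zero_coupling_matches_single_cell_reference(self):
        """With coupling weights 0 the network reduces to independent cells;
        the compiled kernel must track the pure-Python reference integrated
        by an adaptive solver to sub-millivolt accuracy."""
        net = NetworkConfig(N=3, seed=1, g_stn_to_gpe=0.0, g_gpe_to_stn=0.0,
                            stn_iapp_sd=0.0, gpe_eps_sd=0.0)
        cfg = _cfg(net=net, duration_ms=300.0, dt_ms=0.01,
                   stim_onset_ms=9e9, ic_mode="synchronized", ic_seed=123)
        res = integrate(cfg)

        from stngpe.engine import _initial_state, _pack_params
        from stngpe.network import sample_heterogeneity
        iapp, eps = sample_heterogeneity(net, net.seed)
        P = _pack_params(net, cfg.stn_params, cfg.gpe_params, iapp, eps)
        y0 = _initial_state(cfg, P)

        def rhs(t, y):
            d = cell_rhs(NeuronState(*y), cfg.stn_params)
            return [d.v, d.Ca, d.n, d.h, d.r]

        sol = solve_ivp(rhs, (0.0, 300.0), y0[:5, 0], rtol=1e-11, atol=1e-12,
                        dense_output=True, max_step=0.5)
        # compare via the synaptic drive the kernel reports (s of STN cells
        # feeds the LFP); instead check spike times through the LFP proxy:
        # the kernel's first STN cell contributes s(t) to LFP equally, and
        # with zero coupling all three STN cells follow rhs exactly, so the
        # reference voltage crossing times must match recorded spikes.
        v_ref = sol.sol(np.arange(0.0, 300.0, 0.01))[0]
        ref_spikes = []
        above = v_ref >= -10.0
        idx = np.flatnonzero(above[1:] & ~above[:-1]) + 1
        last = -1e9
        for i in idx:
            t = i * 0.01
            if t - last > 2.0:
                ref_spikes.append(t)
                last = t
        got = res.spike_times[res.spike_ids == 0]
        assert len(got) == len(ref_spikes)
        np.testing.assert_allclose(got, ref_spikes, atol=0.5)

    def test_dt_halving_robustness(self):
        """Halving the step changes the post-transient mean R by less than
        the seed-to-seed spread of the same observable."""
        def mean_r(dt, seed):
            cfg = _cfg(net=NetworkConfig(N=20, seed=seed),
                       duration_ms=3000.0, dt_ms=dt, stim_onset_ms=9e9,
                       analysis_start_ms=1500.0, ic_seed=seed + 1)
            return integrate(cfg).summary["R_mean"]

        base = mean_r(0.05, 42)
        fine = mean_r(0.025, 42)
        across_seed = np.std([mean_r(0.05, s) for s in (42, 43, 44)])
        assert abs(base - fine) <= max(2 * across_seed, 0.05)


class TestProtocolAndSweep:
    def test_protocol_matches_brute_force_average(self):
        cfg = _cfg(ctl=ControllerConfig(mode="cDBS", K=0.5))
        out = run_protocol(cfg, n_ramp_runs=3)
        # recompute by hand with the same ramp/seed schedule
        from stngpe.engine import _child_seeds
        ramps = np.linspace(0.0, 2000.0, 3)
        seeds = _child_seeds(cfg.ic_seed, 3)
        vals = []
        for t_ramp, sd in zip(ramps, seeds):
            c = cfg.replace(controller=cfg.controller.replace(T_ramp=float(t_ramp)),
                            ic_seed=sd)
            vals.append(integrate(c).summary["R_mean"])
        assert out["R_mean"] == pytest.approx(np.mean(vals))
        assert out["T_on"] == 1.0          # continuous mode
        assert out["R_mean_sd"] >= 0.0

    def test_sweep_grid_and_resume(self, tmp_path):
        cfg = _cfg(ctl=ControllerConfig(mode="cDBS", K=0.5),
                   duration_ms=800.0, stim_onset_ms=300.0,
                   transient_skip_ms=200.0)
        out_csv = tmp_path / "sweep.csv"
        table = sweep(cfg, {"K": [0.0, 0.5], "GW": [0.0, 2.0]},
                      n_ramp_runs=2, out_csv=out_csv)
        assert len(table) == 4
        assert table["feasible"].all()
        # resume: nothing recomputed, identical result read back
        table2 = sweep(cfg, {"K": [0.0, 0.5], "GW": [0.0, 2.0]},
                       n_ramp_runs=2, out_csv=out_csv)
        assert len(table2) == 4
        np.testing.assert_allclose(np.asarray(table["R_mean"], dtype=float),
                                   np.asarray(table2["R_mean"], dtype=float))

    def test_sweep_flags_infeasible_geometry(self, tmp_path):
        cfg = _cfg(duration_ms=500.0)
        table = sweep(cfg, {"GW": [0.0, 7.6]}, n_ramp_runs=2)
        feas = dict(zip(table["GW"], table["feasible"]))
        assert feas[0.0] and not feas[7.6]
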