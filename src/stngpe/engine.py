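"""Time-stepped integration of the full closed-loop STN-GPe system.

The engine advances all 2N cells (membrane, calcium, three gates, synaptic
output), the resonant LFP filter, the delay buffer and the adaptive gate on
a common fixed step with a classical RK4 scheme; the linear filter uses its
exact per-step propagator and is therefore unconditionally stable.  Pulse
amplitudes are frozen at pulse onsets; the adaptive gate is evaluated only
at local maxima of the filtered LFP, detected online as a sign change of
the discrete derivative.

The hot loop is compiled with numba over flat per-cell parameter arrays.
A pure-Python single-cell reference (:mod:`stngpe.cells`) provides the
independent oracle used by the test suite.

Entry points: :func:`integrate` (one run), :func:`run_protocol` (averaging
over ramp intervals with distinct initial-condition seeds) and
:func:`sweep` (resumable parameter grids).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace as _dc_replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .cells import CellParams, GPE_PARAMS, STN_PARAMS, sigmoid_activation
from .network import NetworkConfig, build_lattice, sample_heterogeneity
from .observables import (DEFAULT_ALPHA_D, DEFAULT_K_F, DEFAULT_PERIOD,
                          administered_stimulation, detect_burst_onsets,
                          filter_propagator, mean_peak_period,
                          order_parameter_trace, stimulation_time_fraction)
from .stimulation import ControllerConfig, PulseTrainConfig

__all__ = ["SimulationConfig", "SimulationResult", "integrate",
           "run_protocol", "sweep"]

_MODE_CODE = {"cDBS": 0, "aDBS": 1, "cpLDF": 2, "apLDF": 3}

# ---------------------------------------------------------------------------
# parameter packing for the compiled kernel
# ---------------------------------------------------------------------------

# column indices of the per-cell parameter matrix
(_CM, _GL, _VL, _GK, _VK, _GNA, _VNA, _GT, _GCA, _VCA, _GAHP,
 _EPS, _KCA, _K1,
 _THM, _SGM, _THH, _SGH, _THN, _SGN, _THR, _SGR, _THA, _SGA, _THS, _SGS,
 _THB, _SGB, _BOFF,
 _TN0, _TN1, _THNT, _SGNT,
 _TH0, _TH1, _THHT, _SGHT,
 _TR0, _TR1, _THRT, _SGRT,
 _PHN, _PHH, _PHR,
 _IAPP,
 _SYNA, _SYNB, _SYNTHG, _SYNTHGH, _SYNSGGH,
 _GIN, _VREV, _ISSTN) = range(53)
_NPAR = 53


def _pack_params(net: NetworkConfig, stn: CellParams, gpe: CellParams,
                 iapp_stn: np.ndarray, eps_gpe: np.ndarray) -> np.ndarray:
    """Flatten per-cell constants into a (2N, NPAR) matrix; STN rows first."""
    N = net.N
    P = np.zeros((2 * N, _NPAR))

    def fill(rows, p: CellParams, syn, g_in, v_rev, is_stn):
        P[rows, _CM] = p.C_m
        P[rows, _GL], P[rows, _VL] = p.g_L, p.v_L
        P[rows, _GK], P[rows, _VK] = p.g_K, p.v_K
        P[rows, _GNA], P[rows, _VNA] = p.g_Na, p.v_Na
        P[rows, _GT] = p.g_T
        P[rows, _GCA], P[rows, _VCA] = p.g_Ca, p.v_Ca
        P[rows, _GAHP] = p.g_AHP
        P[rows, _EPS], P[rows, _KCA], P[rows, _K1] = p.eps, p.k_Ca, p.k_1
        for col_t, col_s, x in ((_THM, _SGM, "m"), (_THH, _SGH, "h"),
                                (_THN, _SGN, "n"), (_THR, _SGR, "r"),
                                (_THA, _SGA, "a"), (_THS, _SGS, "s")):
            P[rows, col_t] = p.theta[x]
            P[rows, col_s] = p.sigma[x]
        P[rows, _THB], P[rows, _SGB] = p.theta_b, p.sigma_b
        P[rows, _BOFF] = 1.0 / (1.0 + math.exp(-p.theta_b / p.sigma_b))
        for c0, c1, ct, cs, x in ((_TN0, _TN1, _THNT, _SGNT, "n"),
                                  (_TH0, _TH1, _THHT, _SGHT, "h"),
                                  (_TR0, _TR1, _THRT, _SGRT, "r")):
            P[rows, c0] = p.tau0[x]
            P[rows, c1] = p.tau1[x]
            P[rows, ct] = p.theta_tau[x]
            P[rows, cs] = p.sigma_tau[x]
        P[rows, _PHN], P[rows, _PHH], P[rows, _PHR] = p.phi["n"], p.phi["h"], p.phi["r"]
        P[rows, _IAPP] = p.I_app
        P[rows, _SYNA], P[rows, _SYNB] = syn.alpha, syn.beta
        P[rows, _SYNTHG] = syn.theta_g
        P[rows, _SYNTHGH], P[rows, _SYNSGGH] = syn.theta_g_H, syn.sigma_g_H
        P[rows, _GIN], P[rows, _VREV] = g_in, v_rev
        P[rows, _ISSTN] = 1.0 if is_stn else 0.0

    stn_rows = np.arange(N)
    gpe_rows = np.arange(N, 2 * N)
    fill(stn_rows, stn, net.stn_synapse, net.g_gpe_to_stn, net.v_gpe_to_stn, True)
    fill(gpe_rows, gpe, net.gpe_synapse, net.g_stn_to_gpe, net.v_stn_to_gpe, False)
    P[stn_rows, _IAPP] = iapp_stn
    P[gpe_rows, _EPS] = eps_gpe
    return P


def _pack_presyn(net: NetworkConfig) -> tuple:
    """Presynaptic index lists: STN cell i <- GPe {i-1,i,i+1}; GPe i <- STN i."""
    N = net.N
    conn = build_lattice(N)
    pre_idx = np.zeros((2 * N, 3), dtype=np.int64)
    npre = np.zeros(2 * N, dtype=np.int64)
    # invert the fan-outs into fan-ins
    for g in range(N):                       # GPe g inhibits 3 STN cells
        for t in conn.gpe_to_stn[g]:
            pre_idx[t, npre[t]] = N + g
            npre[t] += 1
    for s in range(N):                       # STN s excites GPe conn[s]
        t = N + conn.stn_to_gpe[s]
        pre_idx[t, npre[t]] = s
        npre[t] += 1
    return pre_idx, npre


# ---------------------------------------------------------------------------
# compiled kernel
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _deriv(P, pre_idx, npre, v, ca, n, h, r, s, istim,
           dv, dca, dn, dh, dr, ds):
    ncell = v.shape[0]
    for i in range(ncell):
        vi = v[i]
        m_inf = 1.0 / (1.0 + np.exp(-(vi - P[i, _THM]) / P[i, _SGM]))
        s_inf = 1.0 / (1.0 + np.exp(-(vi - P[i, _THS]) / P[i, _SGS]))
        a_inf = 1.0 / (1.0 + np.exp(-(vi - P[i, _THA]) / P[i, _SGA]))

        il = P[i, _GL] * (vi - P[i, _VL])
        ik = P[i, _GK] * n[i] ** 4 * (vi - P[i, _VK])
        ina = P[i, _GNA] * m_inf ** 3 * h[i] * (vi - P[i, _VNA])
        ica = P[i, _GCA] * s_inf ** 2 * (vi - P[i, _VCA])
        iahp = P[i, _GAHP] * (vi - P[i, _VK]) * ca[i] / (ca[i] + P[i, _K1])
        if P[i, _ISSTN] == 1.0:
            b = 1.0 / (1.0 + np.exp((r[i] - P[i, _THB]) / P[i, _SGB])) - P[i, _BOFF]
            it = P[i, _GT] * a_inf ** 3 * b * b * (vi - P[i, _VCA])
        else:
            it = P[i, _GT] * a_inf ** 3 * r[i] * (vi - P[i, _VCA])

        ssum = 0.0
        for j in range(npre[i]):
            ssum += s[pre_idx[i, j]]
        isyn = P[i, _GIN] * (vi - P[i, _VREV]) * ssum

        ist = istim if P[i, _ISSTN] == 1.0 else 0.0
        dv[i] = (-il - ik - ina - it - ica - iahp - isyn + P[i, _IAPP] + ist) / P[i, _CM]
        dca[i] = P[i, _EPS] * (-ica - it - P[i, _KCA] * ca[i])

        n_inf = 1.0 / (1.0 + np.exp(-(vi - P[i, _THN]) / P[i, _SGN]))
        tau_n = P[i, _TN0] + P[i, _TN1] / (1.0 + np.exp(-(vi - P[i, _THNT]) / P[i, _SGNT]))
        dn[i] = P[i, _PHN] * (n_inf - n[i]) / tau_n
        h_inf = 1.0 / (1.0 + np.exp(-(vi - P[i, _THH]) / P[i, _SGH]))
        tau_h = P[i, _TH0] + P[i, _TH1] / (1.0 + np.exp(-(vi - P[i, _THHT]) / P[i, _SGHT]))
        dh[i] = P[i, _PHH] * (h_inf - h[i]) / tau_h
        r_inf = 1.0 / (1.0 + np.exp(-(vi - P[i, _THR]) / P[i, _SGR]))
        if P[i, _TR1] == 0.0:
            tau_r = P[i, _TR0]
        else:
            tau_r = P[i, _TR0] + P[i, _TR1] / (1.0 + np.exp(-(vi - P[i, _THRT]) / P[i, _SGRT]))
        dr[i] = P[i, _PHR] * (r_inf - r[i]) / tau_r

        hs = 1.0 / (1.0 + np.exp(-((vi - P[i, _SYNTHG]) - P[i, _SYNTHGH]) / P[i, _SYNSGGH]))
        ds[i] = P[i, _SYNA] * hs * (1.0 - s[i]) - P[i, _SYNB] * s[i]


@njit(cache=True, fastmath=True)
def _pulse_value(offset, PW, GW, ratio, ipi):
    """Unit waveform at ``offset`` ms after the active pulse onset."""
    if offset < 0.0 or offset >= ipi:
        return 0.0
    if offset < PW:
        return -ratio
    if offset < PW + GW:
        return 0.0
    if offset < (1.0 + ratio) * PW + GW:
        return 1.0
    return 0.0


@njit(cache=True, fastmath=True)
def _run_kernel(P, pre_idx, npre, y0, dt, nsteps,
                mode_code, K, lag, th_on, th_off, t_ramp, t_stim,
                ipi, PW, GW, ratio,
                fE00, fE01, fE10, fE11, ff0, ff1,
                lfp, x, S, gate, A_trace,
                spike_t, spike_id, sp_thresh, sp_refr, nstn):
    ncell = P.shape[0]
    v = y0[0].copy(); ca = y0[1].copy(); n = y0[2].copy()
    h = y0[3].copy(); r = y0[4].copy(); s = y0[5].copy()

    dv1 = np.empty(ncell); dca1 = np.empty(ncell); dn1 = np.empty(ncell)
    dh1 = np.empty(ncell); dr1 = np.empty(ncell); ds1 = np.empty(ncell)
    dv2 = np.empty(ncell); dca2 = np.empty(ncell); dn2 = np.empty(ncell)
    dh2 = np.empty(ncell); dr2 = np.empty(ncell); ds2 = np.empty(ncell)
    dv3 = np.empty(ncell); dca3 = np.empty(ncell); dn3 = np.empty(ncell)
    dh3 = np.empty(ncell); dr3 = np.empty(ncell); ds3 = np.empty(ncell)
    dv4 = np.empty(ncell); dca4 = np.empty(ncell); dn4 = np.empty(ncell)
    dh4 = np.empty(ncell); dr4 = np.empty(ncell); ds4 = np.empty(ncell)
    tv = np.empty(ncell); tca = np.empty(ncell); tn = np.empty(ncell)
    th = np.empty(ncell); tr = np.empty(ncell); ts = np.empty(ncell)

    u = 0.0; udot = 0.0
    adaptive = mode_code == 1 or mode_code == 3
    is_ldf = mode_code == 2 or mode_code == 3
    # stimulation is delivered from its onset; the adaptive logic then
    # switches it off at the first qualifying local maximum
    gate_on = True
    cur_pulse = -1
    A_cur = 0.0
    nspk = 0
    last_spike = np.full(nstn, -1.0e9)

    lfp0 = 0.0
    for i in range(nstn):
        lfp0 += s[i]
    lfp[0] = lfp0 / nstn
    x[0] = 0.0

    for k in range(nsteps):
        t = k * dt
        stim_active = t >= t_stim

        # freeze the amplitude of a newly started pulse
        if stim_active:
            npulse = int((t - t_stim) / ipi + 1e-9)
            if npulse > cur_pulse:
                cur_pulse = npulse
                if t_ramp > 0.0:
                    kr = K * min(1.0, (t - t_stim) / t_ramp)
                else:
                    kr = K
                if is_ldf:
                    jd = k - lag
                    xd = x[jd] if jd >= 0 else 0.0
                    base = kr * (xd - x[k])
                else:
                    base = kr
                if adaptive and not gate_on:
                    A_cur = 0.0
                else:
                    A_cur = base
        A_trace[k] = A_cur

        # stimulation current at the three RK substage times
        if stim_active:
            t_n = t_stim + cur_pulse * ipi
            i_a = A_cur * _pulse_value(t - t_n, PW, GW, ratio, ipi)
            i_b = A_cur * _pulse_value(t + 0.5 * dt - t_n, PW, GW, ratio, ipi)
            i_c = A_cur * _pulse_value(t + dt - t_n, PW, GW, ratio, ipi)
        else:
            i_a = 0.0; i_b = 0.0; i_c = 0.0

        # classical RK4 step of the full network state
        _deriv(P, pre_idx, npre, v, ca, n, h, r, s, i_a,
               dv1, dca1, dn1, dh1, dr1, ds1)
        hdt = 0.5 * dt
        for i in range(ncell):
            tv[i] = v[i] + hdt * dv1[i]; tca[i] = ca[i] + hdt * dca1[i]
            tn[i] = n[i] + hdt * dn1[i]; th[i] = h[i] + hdt * dh1[i]
            tr[i] = r[i] + hdt * dr1[i]; ts[i] = s[i] + hdt * ds1[i]
        _deriv(P, pre_idx, npre, tv, tca, tn, th, tr, ts, i_b,
               dv2, dca2, dn2, dh2, dr2, ds2)
        for i in range(ncell):
            tv[i] = v[i] + hdt * dv2[i]; tca[i] = ca[i] + hdt * dca2[i]
            tn[i] = n[i] + hdt * dn2[i]; th[i] = h[i] + hdt * dh2[i]
            tr[i] = r[i] + hdt * dr2[i]; ts[i] = s[i] + hdt * ds2[i]
        _deriv(P, pre_idx, npre, tv, tca, tn, th, tr, ts, i_b,
               dv3, dca3, dn3, dh3, dr3, ds3)
        for i in range(ncell):
            tv[i] = v[i] + dt * dv3[i]; tca[i] = ca[i] + dt * dca3[i]
            tn[i] = n[i] + dt * dn3[i]; th[i] = h[i] + dt * dh3[i]
            tr[i] = r[i] + dt * dr3[i]; ts[i] = s[i] + dt * ds3[i]
        _deriv(P, pre_idx, npre, tv, tca, tn, th, tr, ts, i_c,
               dv4, dca4, dn4, dh4, dr4, ds4)
        sixth = dt / 6.0
        vmax = 0.0
        for i in range(ncell):
            vold = v[i]
            v[i] += sixth * (dv1[i] + 2.0 * dv2[i] + 2.0 * dv3[i] + dv4[i])
            ca[i] += sixth * (dca1[i] + 2.0 * dca2[i] + 2.0 * dca3[i] + dca4[i])
            n[i] += sixth * (dn1[i] + 2.0 * dn2[i] + 2.0 * dn3[i] + dn4[i])
            h[i] += sixth * (dh1[i] + 2.0 * dh2[i] + 2.0 * dh3[i] + dh4[i])
            r[i] += sixth * (dr1[i] + 2.0 * dr2[i] + 2.0 * dr3[i] + dr4[i])
            s[i] += sixth * (ds1[i] + 2.0 * ds2[i] + 2.0 * ds3[i] + ds4[i])
            av = v[i] if v[i] >= 0.0 else -v[i]
            if av > vmax:
                vmax = av
            # spike detection on STN cells: upward crossing with lockout
            if i < nstn and vold < sp_thresh and v[i] >= sp_thresh:
                tsp = (k + 1) * dt
                if tsp - last_spike[i] > sp_refr:
                    last_spike[i] = tsp
                    if nspk < spike_t.shape[0]:
                        spike_t[nspk] = tsp
                        spike_id[nspk] = i
                        nspk += 1

        # divergence guard: physiological voltages stay within ~[-100, 60]
        # mV; a magnitude this large means the integration has blown up
        # (plain isfinite is unreliable under fastmath)
        if vmax > 1.0e4 or not (vmax <= 1.0e4):
            return -1, nspk

        # raw LFP of the new state; exact filter step driven by the
        # zero-order-held LFP of the step start
        lfp_new = 0.0
        for i in range(nstn):
            lfp_new += s[i]
        lfp_new /= nstn
        lfp[k + 1] = lfp_new
        u_new = fE00 * u + fE01 * udot + ff0 * lfp[k]
        ud_new = fE10 * u + fE11 * udot + ff1 * lfp[k]
        u = u_new; udot = ud_new
        x[k + 1] = udot

        # online local-maximum detection on the filtered LFP (sample k)
        if adaptive and k >= 1 and x[k] > x[k + 1] and x[k] >= x[k - 1]:
            if stim_active:
                if not gate_on and x[k] > th_on:
                    gate_on = True
                elif gate_on and x[k] < th_off:
                    gate_on = False

        # gate and modulation-signal traces at sample k+1
        tk1 = (k + 1) * dt
        if tk1 >= t_stim:
            g_now = (gate_on if adaptive else True)
            gate[k + 1] = 1 if g_now else 0
            if t_ramp > 0.0:
                kr1 = K * min(1.0, (tk1 - t_stim) / t_ramp)
            else:
                kr1 = K
            if g_now:
                if is_ldf:
                    jd = k + 1 - lag
                    xd = x[jd] if jd >= 0 else 0.0
                    S[k + 1] = kr1 * (xd - x[k + 1])
                else:
                    S[k + 1] = kr1
            else:
                S[k + 1] = 0.0
        else:
            gate[k + 1] = 0
            S[k + 1] = 0.0

    A_trace[nsteps] = A_cur
    return 0, nspk


# ---------------------------------------------------------------------------
# configuration and result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of one simulation run."""

    network: NetworkConfig = NetworkConfig()
    controller: ControllerConfig = ControllerConfig()
    pulse: PulseTrainConfig = PulseTrainConfig()
    stn_params: CellParams = STN_PARAMS
    gpe_params: CellParams = GPE_PARAMS

    duration_ms: float = 60_000.0
    stim_onset_ms: float = 20_000.0
    dt_ms: float = 0.05
    transient_skip_ms: float = 30_000.0    # analysis starts this long after onset
    analysis_start_ms: Optional[float] = None  # absolute override
    ic_mode: str = "synchronized"          # or "uniform"

    # resonance set to the default network's own stimulation-free mean LFP
    # period (re-derivable with the calibrate-filter command)
    filter_period_ms: float = 95.7
    filter_alpha_d: float = DEFAULT_ALPHA_D
    filter_k_f: float = DEFAULT_K_F

    spike_threshold_mV: float = -10.0
    spike_refractory_ms: float = 2.0
    isi_gap_ms: float = 25.0
    r_grid_dt_ms: float = 1.0
    record_stride: int = 1
    ic_seed: int = 1

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        if self.record_stride < 1:
            raise ValueError("record stride must be >= 1")
        if self.ic_mode not in ("synchronized", "uniform"):
            raise ValueError("ic_mode must be 'synchronized' or 'uniform'")

    @property
    def analysis_start(self) -> float:
        """Absolute start (ms) of the summary window."""
        if self.analysis_start_ms is not None:
            return self.analysis_start_ms
        if self.stim_onset_ms < self.duration_ms and self.controller.K > 0:
            return min(self.stim_onset_ms + self.transient_skip_ms,
                       self.duration_ms)
        return self.duration_ms / 2.0

    def replace(self, **overrides) -> "SimulationConfig":
        return _dc_replace(self, **overrides)


@dataclass
class SimulationResult:
    """Recorded series (at ``record_stride`` resolution), spikes and summary."""

    config: SimulationConfig
    t: np.ndarray
    lfp: np.ndarray
    x: np.ndarray
    S: np.ndarray
    gate: np.ndarray
    A: np.ndarray
    spike_times: np.ndarray
    spike_ids: np.ndarray
    r_times: np.ndarray
    R: np.ndarray
    summary: Dict[str, float] = field(default_factory=dict)

    def series_frame(self) -> pd.DataFrame:
        """Time-series output as a DataFrame (columns t, lfp, x, R, gate, S, A)."""
        R_interp = np.interp(self.t, self.r_times, self.R,
                             left=np.nan, right=np.nan)
        return pd.DataFrame({"t_ms": self.t, "lfp": self.lfp, "x": self.x,
                             "R": R_interp, "gate": self.gate,
                             "S": self.S, "A": self.A})


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------

def _initial_state(cfg: SimulationConfig, P: np.ndarray) -> np.ndarray:
    """Seeded initial conditions.

    ``ic_mode='synchronized'`` (default) starts all cells hyperpolarized in
    a common state with small voltage jitter, i.e. inside the basin of the
    pathological in-phase bursting rhythm the stimulation is meant to treat;
    this is the study condition.  ``ic_mode='uniform'`` draws voltages
    uniformly in [-80, -40] mV (phases effectively random); gates then sit at
    their steady states, the synaptic variable at its voltage-clamped fixed
    point and Ca at the clamped balance of the calcium currents.
    """
    ncell = P.shape[0]
    rng = np.random.default_rng(cfg.ic_seed)
    if cfg.ic_mode == "synchronized":
        y = np.zeros((6, ncell))
        y[0] = -70.0 + rng.normal(0.0, 2.0, size=ncell)
        y[1] = 0.2          # Ca
        y[2] = 0.05         # n
        y[3] = 0.7          # h
        y[4] = 0.7          # r (T-current deinactivated: ready to rebound)
        y[5] = 0.0          # s
        return y
    v = rng.uniform(-80.0, -40.0, size=ncell)
    y = np.zeros((6, ncell))
    y[0] = v
    for i in range(ncell):
        vi = v[i]
        n_inf = sigmoid_activation(vi, P[i, _THN], P[i, _SGN])
        h_inf = sigmoid_activation(vi, P[i, _THH], P[i, _SGH])
        r_inf = sigmoid_activation(vi, P[i, _THR], P[i, _SGR])
        s_inf = sigmoid_activation(vi, P[i, _THS], P[i, _SGS])
        a_inf = sigmoid_activation(vi, P[i, _THA], P[i, _SGA])
        y[2, i], y[3, i], y[4, i] = n_inf, h_inf, r_inf
        ica = P[i, _GCA] * s_inf ** 2 * (vi - P[i, _VCA])
        if P[i, _ISSTN] == 1.0:
            b = (1.0 / (1.0 + math.exp((r_inf - P[i, _THB]) / P[i, _SGB]))
                 - P[i, _BOFF])
            it = P[i, _GT] * a_inf ** 3 * b * b * (vi - P[i, _VCA])
        else:
            it = P[i, _GT] * a_inf ** 3 * r_inf * (vi - P[i, _VCA])
        y[1, i] = max(0.0, (-ica - it) / P[i, _KCA])
        hh = 1.0 / (1.0 + math.exp(-((vi - P[i, _SYNTHG]) - P[i, _SYNTHGH])
                                   / P[i, _SYNSGGH]))
        ah = P[i, _SYNA] * hh
        y[5, i] = ah / (ah + P[i, _SYNB])
    return y


# ---------------------------------------------------------------------------
# top-level runs
# ---------------------------------------------------------------------------

def integrate(cfg: SimulationConfig) -> SimulationResult:
    """Run one full closed-loop simulation and compute its summary scalars.

    Summary keys: ``R_mean``, ``R_sd``, ``T_on``, ``S_abs_mean``,
    ``lfp_period_ms`` (NaN when the LFP has no usable peaks in the window).
    """
    net = cfg.network
    iapp, eps = sample_heterogeneity(net, net.seed)
    P = _pack_params(net, cfg.stn_params, cfg.gpe_params, iapp, eps)
    pre_idx, npre = _pack_presyn(net)
    y0 = _initial_state(cfg, P)

    dt = cfg.dt_ms
    nsteps = int(round(cfg.duration_ms / dt))
    nrec = nsteps + 1
    lfp = np.zeros(nrec)
    x = np.zeros(nrec)
    S = np.zeros(nrec)
    gate = np.zeros(nrec, dtype=np.uint8)
    A = np.zeros(nrec)
    max_spk = int(net.N * (cfg.duration_ms / 1000.0) * 400) + 1000
    spike_t = np.zeros(max_spk)
    spike_id = np.zeros(max_spk, dtype=np.int64)

    E, f = filter_propagator(cfg.filter_alpha_d, cfg.filter_k_f,
                             2.0 * np.pi / cfg.filter_period_ms, dt)
    ctl, pl = cfg.controller, cfg.pulse
    # K = 0 delivers nothing: report the run as stimulation-free
    stim_onset = cfg.stim_onset_ms if ctl.K > 0 else np.inf
    lag = int(round(ctl.tau / dt))
    status, nspk = _run_kernel(
        P, pre_idx, npre, y0, dt, nsteps,
        _MODE_CODE[ctl.mode], ctl.K, lag, ctl.Th_on, ctl.Th_off,
        ctl.T_ramp, stim_onset,
        pl.interval, pl.PW, pl.GW, pl.ratio,
        E[0, 0], E[0, 1], E[1, 0], E[1, 1], f[0], f[1],
        lfp, x, S, gate, A,
        spike_t, spike_id, cfg.spike_threshold_mV, cfg.spike_refractory_ms,
        net.N)
    if status != 0:
        raise FloatingPointError("numerical blow-up: non-finite network state")
    spike_t, spike_id = spike_t[:nspk], spike_id[:nspk]

    # order-parameter trace from burst-onset phases
    r_times = np.arange(0.0, cfg.duration_ms + cfg.r_grid_dt_ms / 2,
                        cfg.r_grid_dt_ms)
    onset_lists = []
    for j in range(net.N):
        stj = spike_t[spike_id == j]
        onset_lists.append(detect_burst_onsets(stj, cfg.isi_gap_ms))
    R = order_parameter_trace(onset_lists, r_times)

    # summary over the analysis window
    a0 = cfg.analysis_start
    win = slice(int(round(a0 / dt)), nrec)
    rwin = (r_times >= a0) & np.isfinite(R)
    summary: Dict[str, float] = {}
    summary["R_mean"] = float(np.mean(R[rwin])) if rwin.any() else float("nan")
    summary["R_sd"] = float(np.std(R[rwin])) if rwin.any() else float("nan")
    summary["T_on"] = stimulation_time_fraction(gate, win)
    summary["S_abs_mean"] = administered_stimulation(S, win)
    try:
        summary["lfp_period_ms"] = mean_peak_period(lfp[win], dt)
    except ValueError:
        summary["lfp_period_ms"] = float("nan")

    stride = cfg.record_stride
    return SimulationResult(
        config=cfg,
        t=np.arange(nrec)[::stride] * dt,
        lfp=lfp[::stride], x=x[::stride], S=S[::stride],
        gate=gate[::stride], A=A[::stride],
        spike_times=spike_t, spike_ids=spike_id,
        r_times=r_times, R=R, summary=summary)


def _child_seeds(seed: int, n: int) -> List[int]:
    """Deterministic per-run seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def run_protocol(cfg: SimulationConfig, n_ramp_runs: int = 10) -> Dict[str, float]:
    """Average summaries over runs with evenly spaced ramp intervals.

    T_ramp takes ``n_ramp_runs`` evenly spaced values in [0, 2000] ms; each
    run uses a distinct initial-condition seed (the network heterogeneity is
    fixed by the network seed).  Returns mean and sd of ``R_mean``, ``T_on``
    and ``S_abs_mean`` plus the per-run values.
    """
    if n_ramp_runs < 2:
        raise ValueError("need at least 2 ramp runs")
    ramps = np.linspace(0.0, 2000.0, n_ramp_runs)
    seeds = _child_seeds(cfg.ic_seed, n_ramp_runs)
    rows = []
    for t_ramp, sd in zip(ramps, seeds):
        run_cfg = cfg.replace(controller=cfg.controller.replace(T_ramp=float(t_ramp)),
                              ic_seed=sd)
        res = integrate(run_cfg)
        rows.append(res.summary)
    out: Dict[str, float] = {"n_runs": n_ramp_runs}
    for key in ("R_mean", "T_on", "S_abs_mean", "lfp_period_ms"):
        vals = np.asarray([row[key] for row in rows])
        out[key] = float(np.nanmean(vals))
        out[key + "_sd"] = float(np.nanstd(vals))
    out["runs"] = rows
    return out


def sweep(cfg: SimulationConfig, grid: Dict[str, Sequence],
          n_ramp_runs: int = 10,
          out_csv: Optional[Path] = None) -> pd.DataFrame:
    """Run :func:`run_protocol` over a cartesian parameter grid.

    ``grid`` maps controller/pulse field names (``K``, ``tau``, ``Th_on``,
    ``Th_off``, ``GW``) to value lists.  With ``out_csv`` the sweep is
    resumable: rows already present in the file are skipped.  Grid points
    with infeasible pulse geometry (GW beyond the monophasic limit) are
    flagged in the ``feasible`` column and not simulated.
    """
    from .stimulation import monophasic_gap_threshold

    keys = list(grid)
    done = set()
    rows: List[Dict] = []
    if out_csv is not None and Path(out_csv).exists():
        prev = pd.read_csv(out_csv)
        rows = prev.to_dict("records")
        done = {tuple(row[k] for k in keys) for row in rows}
    for values in itertools.product(*(grid[k] for k in keys)):
        if tuple(values) in done:
            continue
        point = dict(zip(keys, values))
        ctl = cfg.controller
        pl = cfg.pulse
        for k, val in point.items():
            if k == "GW":
                pl = pl.replace(GW=float(val))
            elif k in ("K", "tau", "Th_on", "Th_off"):
                ctl = ctl.replace(**{k: float(val)})
            else:
                raise ValueError(f"unknown sweep axis {k!r}")
        row = dict(point)
        if pl.GW > monophasic_gap_threshold(pl.F, pl.PW):
            row.update(feasible=False)
        else:
            res = run_protocol(cfg.replace(controller=ctl, pulse=pl), n_ramp_runs)
            row.update(feasible=True,
                       R_mean=res["R_mean"], R_mean_sd=res["R_mean_sd"],
                       T_on=res["T_on"], T_on_sd=res["T_on_sd"],
                       S_abs_mean=res["S_abs_mean"],
                       S_abs_mean_sd=res["S_abs_mean_sd"])
        rows.append(row)
        if out_csv is not None:
            pd.DataFrame(rows).to_csv(out_csv, index=False)
    return pd.DataFrame(rows)
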