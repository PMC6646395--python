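"""LFP, online filtering, burst phases, order parameter and dose metrics.

The raw LFP is the population mean of the STN synaptic variables.  It is
filtered online by a resonant damped oscillator::

    u'' + alpha_d u' + omega^2 u = k_f * LFP(t)

whose output ``x = u'`` has zero phase shift relative to the input at
resonance and unit gain there when ``k_f = alpha_d``.  The default resonance
period is the 103 ms mean period of the stimulation-free LFP oscillation
(~10 Hz); :func:`mean_peak_period` re-estimates it from a run.

Neuronal phases are tied to burst onsets (first spikes of bursts): the phase
of neuron j advances by 2*pi per inter-burst interval, piecewise linearly,
and the Kuramoto-type order parameter is the modulus of the population-mean
unit phasor.  Neurons outside their onset range at a given time are excluded
from the average at that time.

Dose metrics: T_on is the fraction of the analysis window with the adaptive
gate on; <|S|> is the time-averaged absolute amplitude-modulation signal
(S = K while on for the DBS modes, the delayed-feedback signal for LDF).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.linalg import expm
from scipy.signal import find_peaks

__all__ = [
    "FilterState",
    "filter_propagator",
    "compute_lfp",
    "filter_step",
    "detect_spikes",
    "detect_burst_onsets",
    "neuron_phase",
    "phase_trace",
    "order_parameter",
    "order_parameter_trace",
    "mean_peak_period",
    "stimulation_time_fraction",
    "administered_stimulation",
]

#: default resonance period (ms) of the LFP filter
DEFAULT_PERIOD = 103.0
DEFAULT_ALPHA_D = 0.008
DEFAULT_K_F = 0.008


@dataclass
class FilterState:
    """Damped-oscillator filter state; output is ``x = udot``."""

    u: float = 0.0
    udot: float = 0.0
    alpha_d: float = DEFAULT_ALPHA_D
    k_f: float = DEFAULT_K_F
    period: float = DEFAULT_PERIOD   # ms; omega = 2*pi/period

    @property
    def omega(self) -> float:
        return 2.0 * np.pi / self.period

    @property
    def x(self) -> float:
        return self.udot


def filter_propagator(alpha_d: float, k_f: float, omega: float,
                      dt: float) -> Tuple[np.ndarray, np.ndarray]:
    """Exact one-step propagator of the filter under zero-order-hold input.

    Returns ``(E, f)`` with state update ``[u, udot] <- E @ [u, udot] +
    f * LFP``.  Exact for piecewise-constant input, hence unconditionally
    stable at any step size.
    """
    A = np.array([[0.0, 1.0], [-omega ** 2, -alpha_d]])
    B = np.array([0.0, k_f])
    E = expm(A * dt)
    f = np.linalg.solve(A, (E - np.eye(2)) @ B)
    return E, f


def compute_lfp(s_stn: np.ndarray) -> float:
    """Raw LFP: arithmetic mean of the STN synaptic variables."""
    s_stn = np.asarray(s_stn)
    if s_stn.size == 0:
        raise ValueError("empty synaptic-variable vector")
    return float(s_stn.mean())


def filter_step(state: FilterState, lfp: float, dt: float) -> FilterState:
    """Advance the filter by one step of size ``dt`` with input ``lfp``.

    Uses the exact propagator of the linear system (input held constant over
    the step).  Returns the new state; its ``.x`` is the filtered LFP.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    E, f = filter_propagator(state.alpha_d, state.k_f, state.omega, dt)
    u, udot = E @ np.array([state.u, state.udot]) + f * lfp
    return FilterState(u=u, udot=udot, alpha_d=state.alpha_d,
                       k_f=state.k_f, period=state.period)


# ---------------------------------------------------------------------------
# spikes, bursts, phases
# ---------------------------------------------------------------------------

def detect_spikes(v: np.ndarray, dt: float, threshold: float = -10.0,
                  refractory: float = 2.0) -> np.ndarray:
    """Spike times from a voltage trace: upward threshold crossings with a
    refractory lockout (ms)."""
    v = np.asarray(v)
    up = np.flatnonzero((v[1:] >= threshold) & (v[:-1] < threshold)) + 1
    times = up * dt
    if len(times) == 0:
        return times.astype(float)
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] > refractory:
            kept.append(t)
    return np.asarray(kept)


def detect_burst_onsets(spike_times: Sequence[float], isi_gap: float = 25.0) -> np.ndarray:
    """Burst onsets: a spike opens a burst iff it is the first spike or
    follows its predecessor by more than ``isi_gap`` ms."""
    t = np.asarray(spike_times, dtype=float)
    if t.size == 0:
        return t
    if np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted")
    keep = np.empty(t.size, dtype=bool)
    keep[0] = True
    keep[1:] = np.diff(t) > isi_gap
    return t[keep]


def neuron_phase(onsets: Sequence[float], t: float) -> float:
    """Piecewise-linear burst phase: ``psi(t_n) = 2*pi*n`` at onsets, linear
    in between.  Undefined (ValueError) outside the onset range."""
    o = np.asarray(onsets, dtype=float)
    if o.size < 2 or t < o[0] or t > o[-1]:
        raise ValueError("t outside the neuron's burst-onset range")
    n = int(np.searchsorted(o, t, side="right")) - 1
    if n == o.size - 1:          # t exactly at the last onset
        return 2.0 * np.pi * n
    return 2.0 * np.pi * (n + (t - o[n]) / (o[n + 1] - o[n]))


def phase_trace(onsets: Sequence[float], times: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`neuron_phase` over a time grid.

    Returns ``(psi, valid)``; entries with ``valid == False`` fall outside
    the onset range and carry no phase.
    """
    o = np.asarray(onsets, dtype=float)
    times = np.asarray(times, dtype=float)
    psi = np.full(times.shape, np.nan)
    if o.size < 2:
        return psi, np.zeros(times.shape, dtype=bool)
    valid = (times >= o[0]) & (times <= o[-1])
    idx = np.clip(np.searchsorted(o, times[valid], side="right") - 1, 0, o.size - 2)
    frac = (times[valid] - o[idx]) / (o[idx + 1] - o[idx])
    psi[valid] = 2.0 * np.pi * (idx + frac)
    return psi, valid


def order_parameter(phases: np.ndarray) -> float:
    """Kuramoto order parameter ``R = |mean(exp(i*psi))|`` in [0, 1]."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("empty phase vector")
    return float(np.abs(np.exp(1j * phases).mean()))


def order_parameter_trace(onset_lists: List[np.ndarray],
                          times: np.ndarray) -> np.ndarray:
    """R(t) over a time grid from per-neuron burst-onset lists.

    At each time, neurons whose phase is undefined (before their first or
    after their last onset) are excluded from the phasor average; R is NaN
    where no neuron has a defined phase.
    """
    times = np.asarray(times, dtype=float)
    re = np.zeros(times.shape)
    im = np.zeros(times.shape)
    cnt = np.zeros(times.shape)
    for onsets in onset_lists:
        psi, valid = phase_trace(onsets, times)
        if not valid.any():
            continue
        re[valid] += np.cos(psi[valid])
        im[valid] += np.sin(psi[valid])
        cnt[valid] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.hypot(re, im) / cnt
    R[cnt == 0] = np.nan
    return R


def mean_peak_period(trace: np.ndarray, dt: float,
                     min_period: float = 20.0) -> float:
    """Mean inter-peak interval (ms) of an oscillatory trace.

    Peaks are local maxima separated by at least ``min_period`` ms and above
    the trace mean, which makes the estimate robust to small ripples.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 3:
        raise ValueError("trace too short")
    peaks, _ = find_peaks(trace, distance=max(1, int(round(min_period / dt))),
                          height=float(trace.mean()))
    if len(peaks) < 2:
        raise ValueError("fewer than two peaks found")
    return float(np.diff(peaks).mean() * dt)


# ---------------------------------------------------------------------------
# dose metrics
# ---------------------------------------------------------------------------

def stimulation_time_fraction(gate: np.ndarray, window: slice = slice(None)) -> float:
    """Fraction of samples in the window with the gate on."""
    g = np.asarray(gate)[window]
    if g.size == 0:
        raise ValueError("empty analysis window")
    return float(np.count_nonzero(g) / g.size)


def administered_stimulation(S: np.ndarray, window: slice = slice(None)) -> float:
    """Time-averaged absolute amplitude-modulation signal ``<|S|>``.

    ``S`` must already be zero while the gate is off.
    """
    s = np.asarray(S, dtype=float)[window]
    if s.size == 0:
        raise ValueError("empty analysis window")
    return float(np.abs(s).mean())
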