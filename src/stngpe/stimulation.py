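"""Stimulation waveforms and closed-loop controllers.

Four stimulation modes act on the STN population:

* ``cDBS``  — continuous high-frequency pulse train, constant intensity K;
* ``aDBS``  — the same train gated on/off by filtered-LFP thresholds;
* ``cpLDF`` — pulse train whose amplitude is modulated by the linear
  delayed-feedback signal ``S(t) = K (x(t - tau) - x(t))``;
* ``apLDF`` — cpLDF gated on/off by the same thresholds.

The carrier is an asymmetric charge-balanced biphasic pulse: a short cathodic
first phase of width PW and relative amplitude -10, an optional zero-current
interphase gap GW, and a long anodic recharging phase of width 10*PW and
relative amplitude +1.  Pulses repeat at frequency F; the amplitude factor
A(t_n) is frozen at each pulse onset t_n = n*1000/F.

The adaptive gate is evaluated only at local maxima of the filtered LFP x:
off -> on when a maximum exceeds Th_on, on -> off when one falls below
Th_off (hysteresis for Th_on > Th_off).  After the stimulation onset the
intensity K ramps linearly from 0 over T_ramp milliseconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

__all__ = [
    "MODES",
    "PulseTrainConfig",
    "ControllerConfig",
    "GateState",
    "pulse_shape",
    "max_charge_balanced_gap",
    "monophasic_gap_threshold",
    "stimulation_current",
    "ldf_amplitude",
    "gate_update",
    "ramp_factor",
]

MODES = ("cDBS", "aDBS", "cpLDF", "apLDF")

#: relative amplitude of the cathodic first phase; the anodic phase has
#: relative amplitude +1 over ``ratio * PW`` so that charge balances exactly.
CATHODIC_AMPLITUDE = -10.0


@dataclass(frozen=True)
class PulseTrainConfig:
    """Geometry of the charge-balanced biphasic pulse train."""

    F: float = 130.0       # Hz, pulses per second
    PW: float = 0.2        # ms, first (cathodic) phase width
    GW: float = 0.0        # ms, interphase gap
    ratio: float = 10.0    # second phase lasts ratio*PW at amplitude 1 vs -ratio

    def __post_init__(self) -> None:
        if self.F <= 0:
            raise ValueError("pulse frequency F must be positive")
        if self.PW <= 0:
            raise ValueError("pulse width PW must be positive")
        if self.GW < 0:
            raise ValueError("interphase gap GW must be nonnegative")
        if self.ratio <= 0:
            raise ValueError("phase-duration ratio must be positive")

    @property
    def interval(self) -> float:
        """Inter-pulse interval 1000/F in ms."""
        return 1000.0 / self.F

    def replace(self, **overrides) -> "PulseTrainConfig":
        return _dc_replace(self, **overrides)


@dataclass(frozen=True)
class ControllerConfig:
    """Closed-loop controller: mode, intensity, delay, thresholds, ramp."""

    mode: str = "cDBS"
    K: float = 0.0           # dimensionless stimulation intensity
    tau: float = 0.0         # ms, feedback delay (LDF modes)
    Th_on: float = -np.inf   # filtered-LFP units (adaptive modes)
    Th_off: float = -np.inf
    T_ramp: float = 0.0      # ms, linear intensity ramp after onset

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown stimulation mode {self.mode!r}")
        if self.K < 0:
            raise ValueError("stimulation intensity K must be nonnegative")
        if self.tau < 0:
            raise ValueError("delay tau must be nonnegative")
        if self.Th_on < self.Th_off:
            raise ValueError("Th_on must be >= Th_off")
        if not 0.0 <= self.T_ramp <= 2000.0:
            raise ValueError("T_ramp must lie in [0, 2000] ms")

    @property
    def adaptive(self) -> bool:
        return self.mode in ("aDBS", "apLDF")

    @property
    def delayed_feedback(self) -> bool:
        return self.mode in ("cpLDF", "apLDF")

    def replace(self, **overrides) -> "ControllerConfig":
        return _dc_replace(self, **overrides)


@dataclass
class GateState:
    """On/off state of the adaptive gate with its last toggle time."""

    on: bool = False
    last_toggle: float = np.nan


# ---------------------------------------------------------------------------
# pulse geometry
# ---------------------------------------------------------------------------

def pulse_shape(t_offset: float, cfg: PulseTrainConfig) -> float:
    """Unit waveform value at ``t_offset`` ms after a pulse onset.

    -10 in the cathodic first phase, 0 in the interphase gap, +1 in the
    anodic recharging phase, 0 for the rest of the inter-pulse interval.
    """
    if not 0.0 <= t_offset < cfg.interval:
        raise ValueError("t_offset outside the inter-pulse interval")
    if t_offset < cfg.PW:
        return -cfg.ratio
    if t_offset < cfg.PW + cfg.GW:
        return 0.0
    if t_offset < (1.0 + cfg.ratio) * cfg.PW + cfg.GW:
        return 1.0
    return 0.0


def max_charge_balanced_gap(F: float, PW: float, ratio: float = 10.0) -> float:
    """Largest interphase gap (ms) for which the full biphasic pulse fits the
    inter-pulse interval, ``1000/F - (1+ratio)*PW``.

    Beyond this the recharging phase is truncated and the pulse is no longer
    charge balanced.  Infeasible geometry (negative result) is reported as 0
    with a warning.
    """
    if F <= 0 or PW <= 0:
        raise ValueError("F and PW must be positive")
    gap = 1000.0 / F - (1.0 + ratio) * PW
    if gap < 0:
        warnings.warn("pulse geometry infeasible: biphasic pulse does not fit "
                      "the inter-pulse interval", stacklevel=2)
        return 0.0
    return gap


def monophasic_gap_threshold(F: float, PW: float) -> float:
    """Gap width (ms) beyond which no recharging phase fits at all and the
    pulse turns monophasic: ``1000/F - PW``."""
    if F <= 0 or PW <= 0:
        raise ValueError("F and PW must be positive")
    return 1000.0 / F - PW


def stimulation_current(t: float, amplitude_at_onset: float,
                        cfg: PulseTrainConfig, t_onset: float = 0.0) -> float:
    """Stimulation current ``A(t_n) * pulse_shape(t - t_n)`` in pA/um^2.

    ``amplitude_at_onset`` is the factor frozen at the onset ``t_onset`` of
    the pulse containing ``t``.
    """
    return amplitude_at_onset * pulse_shape(t - t_onset, cfg)


# ---------------------------------------------------------------------------
# controllers
# ---------------------------------------------------------------------------

def ldf_amplitude(x_history: np.ndarray, t_index: int, K: float,
                  tau: float, dt: float) -> float:
    """Linear delayed-feedback signal ``S = K (x(t - tau) - x(t))``.

    ``x_history`` holds the filtered LFP on the integration grid up to and
    including ``t_index``; the delayed sample is looked up ``round(tau/dt)``
    samples back (zero for indices before the start of the record).
    """
    lag = int(round(tau / dt))
    if lag > len(x_history) - 1 and t_index - lag < -len(x_history):
        raise ValueError("delay tau exceeds the recorded history")
    x_now = x_history[t_index]
    j = t_index - lag
    x_del = x_history[j] if j >= 0 else 0.0
    return K * (x_del - x_now)


def gate_update(state: GateState, local_max_value: float,
                Th_on: float, Th_off: float, t: float = np.nan) -> GateState:
    """Hysteresis update of the adaptive gate at a filtered-LFP local maximum.

    off -> on iff the maximum exceeds Th_on; on -> off iff it falls below
    Th_off; otherwise unchanged.
    """
    if Th_on < Th_off:
        raise ValueError("Th_on must be >= Th_off")
    if not state.on and local_max_value > Th_on:
        return GateState(on=True, last_toggle=t)
    if state.on and local_max_value < Th_off:
        return GateState(on=False, last_toggle=t)
    return state


def ramp_factor(t_since_onset: float, T_ramp: float) -> float:
    """Linear intensity ramp: ``min(1, t/T_ramp)``, 1 for ``T_ramp = 0``."""
    if t_since_onset < 0:
        raise ValueError("t_since_onset must be nonnegative")
    if T_ramp <= 0:
        return 1.0
    return min(1.0, t_since_onset / T_ramp)
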