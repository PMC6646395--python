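"""Single-cell dynamics of STN and GPe model neurons.

Conductance-based point neurons of the subthalamic nucleus (STN) and external
globus pallidus (GPe) in the Terman–Rubin tradition.  Each cell carries a
membrane potential ``v`` (mV), an intracellular calcium concentration ``Ca``
(model units) and three gating variables ``n``, ``h``, ``r``::

    C_m v' = -I_L - I_K - I_Na - I_T - I_Ca - I_AHP - I_syn + I_app + I_stim
    [Ca]'  = eps * (-I_Ca - I_T - k_Ca [Ca])
    X'     = phi_X (X_inf(v) - X) / tau_X(v),     X in {n, h, r}

with logistic steady-state curves ``X_inf`` and voltage-dependent time
constants ``tau_X``.  The low-threshold calcium current I_T differs between
the populations: STN cells use the rectified activation ``b_inf(r)``, GPe
cells use the gating variable ``r`` directly; for GPe cells ``tau_r`` is a
constant.

The numeric defaults in :data:`STN_PARAMS` / :data:`GPE_PARAMS` follow the
published Terman–Rubin subthalamopallidal constants for every value the
model lineage fixes.  The GPe bias current (here -2 pA/um^2, placing GPe in
a driven, phasic regime) and the inhibitory synapse kinetics were fixed once
by calibrating the stimulation-free coupled network to its documented
synchronized ~10 Hz bursting regime; docs/methods.md details that
calibration.  Every constant can be overridden through
:meth:`CellParams.replace` or the run configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Dict

from scipy.special import expit

__all__ = [
    "CellParams",
    "NeuronState",
    "STN_PARAMS",
    "GPE_PARAMS",
    "sigmoid_activation",
    "voltage_time_constant",
    "b_inf",
    "membrane_currents",
    "cell_rhs",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellParams:
    """Full constant set of one model neuron.

    Units follow the model convention: conductances in nS/um^2, voltages in
    mV, currents in pA/um^2, capacitance in pF/um^2, rates in 1/ms.
    """

    population: str                      # "STN" or "GPe"
    C_m: float = 1.0

    # maximal conductances and reversal potentials
    g_L: float = 0.0
    g_K: float = 0.0
    g_Na: float = 0.0
    g_T: float = 0.0
    g_Ca: float = 0.0
    g_AHP: float = 0.0
    v_L: float = 0.0
    v_K: float = 0.0
    v_Na: float = 0.0
    v_Ca: float = 0.0

    # calcium dynamics
    eps: float = 0.0                     # 1/ms
    k_Ca: float = 0.0
    k_1: float = 0.0

    # steady-state sigmoid constants, X in {n, h, r, m, s, a}
    theta: Dict[str, float] = field(default_factory=dict)
    sigma: Dict[str, float] = field(default_factory=dict)
    # b_inf constants (STN I_T only)
    theta_b: float = 0.0
    sigma_b: float = 1.0

    # time-constant parameters, X in {n, h, r}
    tau0: Dict[str, float] = field(default_factory=dict)
    tau1: Dict[str, float] = field(default_factory=dict)
    theta_tau: Dict[str, float] = field(default_factory=dict)
    sigma_tau: Dict[str, float] = field(default_factory=dict)

    # gating rate scales
    phi: Dict[str, float] = field(default_factory=dict)

    # bias current
    I_app: float = 0.0

    def __post_init__(self) -> None:
        if self.population not in ("STN", "GPe"):
            raise ValueError(f"unknown population tag {self.population!r}")
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        for name in ("g_L", "g_K", "g_Na", "g_T", "g_Ca", "g_AHP"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for x, s in self.sigma.items():
            if s == 0:
                raise ValueError(f"sigma[{x!r}] must be nonzero")
        if self.sigma_b == 0:
            raise ValueError("sigma_b must be nonzero")
        for x in self.tau0:
            t0, t1 = self.tau0[x], self.tau1.get(x, 0.0)
            if t0 <= 0 or t0 + t1 <= 0:
                raise ValueError(f"tau asymptotes for {x!r} must be positive")

    def replace(self, **overrides) -> "CellParams":
        """Return a copy with the given constants overridden."""
        return _dc_replace(self, **overrides)


@dataclass
class NeuronState:
    """Dynamical variables of one neuron."""

    v: float
    Ca: float
    n: float
    h: float
    r: float


# ---------------------------------------------------------------------------
# default parameter sets (Terman–Rubin subthalamopallidal constants)
# ---------------------------------------------------------------------------

STN_PARAMS = CellParams(
    population="STN",
    C_m=1.0,
    g_L=2.25, v_L=-60.0,
    g_K=45.0, v_K=-80.0,
    g_Na=37.5, v_Na=55.0,
    g_T=0.5,
    g_Ca=0.5, v_Ca=140.0,
    g_AHP=9.0,
    eps=3.75e-5, k_Ca=22.5, k_1=15.0,
    theta={"m": -30.0, "h": -39.0, "n": -32.0, "r": -67.0, "a": -63.0, "s": -39.0},
    sigma={"m": 15.0, "h": -3.1, "n": 8.0, "r": -2.0, "a": 7.8, "s": 8.0},
    theta_b=0.4, sigma_b=-0.1,
    tau0={"n": 1.0, "h": 1.0, "r": 40.0},
    tau1={"n": 100.0, "h": 500.0, "r": 17.5},
    theta_tau={"n": -80.0, "h": -57.0, "r": 68.0},
    sigma_tau={"n": -26.0, "h": -3.0, "r": -2.2},
    phi={"n": 0.75, "h": 0.75, "r": 0.2},
    I_app=10.0,
)

GPE_PARAMS = CellParams(
    population="GPe",
    C_m=1.0,
    g_L=0.1, v_L=-55.0,
    g_K=30.0, v_K=-80.0,
    g_Na=120.0, v_Na=55.0,
    g_T=0.5,
    g_Ca=0.15, v_Ca=120.0,
    g_AHP=30.0,
    eps=0.0055, k_Ca=15.0, k_1=30.0,
    theta={"m": -37.0, "h": -58.0, "n": -50.0, "r": -70.0, "a": -57.0, "s": -35.0},
    sigma={"m": 10.0, "h": -12.0, "n": 14.0, "r": -2.0, "a": 2.0, "s": 2.0},
    theta_b=0.4, sigma_b=-0.1,          # unused by the GPe I_T variant
    tau0={"n": 0.05, "h": 0.05, "r": 30.0},
    tau1={"n": 0.27, "h": 0.27, "r": 0.0},   # tau_r constant for GPe
    theta_tau={"n": -40.0, "h": -40.0, "r": 0.0},
    sigma_tau={"n": -12.0, "h": -12.0, "r": -1.0},
    phi={"n": 0.05, "h": 0.05, "r": 1.0},
    I_app=-2.0,
)


# ---------------------------------------------------------------------------
# elementary functions
# ---------------------------------------------------------------------------

def sigmoid_activation(v: float, theta: float, sigma: float) -> float:
    """Logistic steady-state curve ``X_inf(v) = 1/(1+exp[-(v-theta)/sigma])``."""
    if sigma == 0:
        raise ValueError("sigma must be nonzero")
    return float(expit((v - theta) / sigma))


def voltage_time_constant(v: float, tau0: float, tau1: float,
                          theta_tau: float, sigma_tau: float) -> float:
    """Voltage-dependent time constant ``tau0 + tau1/(1+exp[-(v-theta)/sigma])``."""
    if tau0 <= 0 or tau0 + tau1 <= 0:
        raise ValueError("time-constant asymptotes must be positive")
    return tau0 + tau1 * float(expit((v - theta_tau) / sigma_tau))


def b_inf(r: float, theta_b: float, sigma_b: float) -> float:
    """Rectified activation of the STN low-threshold calcium current.

    ``b_inf(r) = 1/(1+exp[(r-theta_b)/sigma_b]) - 1/(1+exp[-theta_b/sigma_b])``;
    the constant offset makes ``b_inf(0) = 0`` exactly.
    """
    if sigma_b == 0:
        raise ValueError("sigma_b must be nonzero")
    return float(expit(-(r - theta_b) / sigma_b) - expit(theta_b / sigma_b))


# ---------------------------------------------------------------------------
# currents and right-hand side
# ---------------------------------------------------------------------------

def membrane_currents(state: NeuronState, p: CellParams) -> Dict[str, float]:
    """All intrinsic membrane currents (pA/um^2) at the given state.

    Returns a dict with keys ``L, K, Na, T, Ca, AHP``.  The low-threshold
    calcium current uses the population-specific form.
    """
    v, Ca = state.v, state.Ca
    m_inf = sigmoid_activation(v, p.theta["m"], p.sigma["m"])
    s_inf = sigmoid_activation(v, p.theta["s"], p.sigma["s"])
    a_inf = sigmoid_activation(v, p.theta["a"], p.sigma["a"])

    I_L = p.g_L * (v - p.v_L)
    I_K = p.g_K * state.n ** 4 * (v - p.v_K)
    I_Na = p.g_Na * m_inf ** 3 * state.h * (v - p.v_Na)
    I_Ca = p.g_Ca * s_inf ** 2 * (v - p.v_Ca)
    I_AHP = p.g_AHP * (v - p.v_K) * (Ca / (Ca + p.k_1))
    if p.population == "STN":
        I_T = p.g_T * a_inf ** 3 * b_inf(state.r, p.theta_b, p.sigma_b) ** 2 * (v - p.v_Ca)
    else:
        I_T = p.g_T * a_inf ** 3 * state.r * (v - p.v_Ca)
    return {"L": I_L, "K": I_K, "Na": I_Na, "T": I_T, "Ca": I_Ca, "AHP": I_AHP}


def cell_rhs(state: NeuronState, p: CellParams,
             I_syn: float = 0.0, I_stim: float = 0.0) -> NeuronState:
    """Time derivative (v', Ca', n', h', r') of one neuron.

    ``I_syn`` and ``I_stim`` are the synaptic and stimulation currents
    entering the membrane equation; ``I_stim`` enters with a plus sign
    (depolarizing for positive values), ``I_syn`` with a minus sign.
    """
    for val in (state.v, state.Ca, state.n, state.h, state.r):
        if not math.isfinite(val):
            raise ValueError("non-finite neuron state")
    cur = membrane_currents(state, p)
    v = state.v
    dv = (-cur["L"] - cur["K"] - cur["Na"] - cur["T"] - cur["Ca"] - cur["AHP"]
          - I_syn + p.I_app + I_stim) / p.C_m
    dCa = p.eps * (-cur["Ca"] - cur["T"] - p.k_Ca * state.Ca)

    def gate_deriv(x_name: str, x_val: float) -> float:
        x_inf = sigmoid_activation(v, p.theta[x_name], p.sigma[x_name])
        tau = voltage_time_constant(v, p.tau0[x_name], p.tau1[x_name],
                                    p.theta_tau[x_name], p.sigma_tau[x_name])
        return p.phi[x_name] * (x_inf - x_val) / tau

    return NeuronState(
        v=dv,
        Ca=dCa,
        n=gate_deriv("n", state.n),
        h=gate_deriv("h", state.h),
        r=gate_deriv("r", state.r),
    )
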