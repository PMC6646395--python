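"""STN-GPe network topology, synapses and cell-to-cell heterogeneity.

The two populations sit on 1-D ring lattices of equal size N.  Each STN
neuron excites the GPe neuron at the same lattice position; each GPe neuron
inhibits the three neighboring STN neurons (centered neighborhood, indices
wrapping modulo N).  Synaptic gating follows first-order kinetics driven by
the presynaptic voltage::

    s' = alpha * H_inf(v_pre - theta_g) * (1 - s) - beta * s
    H_inf(x) = 1/(1+exp[-(x - theta_g_H)/sigma_g_H])

and the synaptic current on a postsynaptic cell is
``I_syn = g * (v_post - v_rev) * sum_j s_j`` over its presynaptic pool.

Heterogeneity: the STN bias currents I_app are Gaussian with mean
10 pA/um^2 and sd 0.015 pA/um^2; the GPe calcium rate constants eps are
Gaussian with mean 0.0055 1/ms and sd 2e-5 1/ms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Tuple

import numpy as np
from scipy.special import expit

__all__ = [
    "SynapseParams",
    "NetworkConfig",
    "Connectivity",
    "build_lattice",
    "synaptic_current",
    "synapse_rhs",
    "sample_heterogeneity",
    "STN_SYNAPSE",
    "GPE_SYNAPSE",
]


@dataclass(frozen=True)
class SynapseParams:
    """First-order synapse kinetics of one presynaptic population."""

    alpha: float        # 1/ms, activation rate
    beta: float         # 1/ms, decay rate
    theta_g: float      # mV, presynaptic voltage offset
    theta_g_H: float    # mV, H_inf midpoint
    sigma_g_H: float    # mV, H_inf slope

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("synapse rates must be nonnegative")
        if self.sigma_g_H == 0:
            raise ValueError("sigma_g_H must be nonzero")


# Fast excitatory STN output (Terman–Rubin kinetics); slowly decaying
# inhibitory GPe output.  The slow GABAergic decay (1/beta = 50 ms) is the
# calibrated value that sustains the in-phase ~10 Hz rebound rhythm of the
# coupled network; see docs/methods.md.
STN_SYNAPSE = SynapseParams(alpha=5.0, beta=1.0, theta_g=30.0,
                            theta_g_H=-39.0, sigma_g_H=8.0)
GPE_SYNAPSE = SynapseParams(alpha=2.0, beta=0.02, theta_g=20.0,
                            theta_g_H=-57.0, sigma_g_H=2.0)


@dataclass(frozen=True)
class NetworkConfig:
    """Population sizes, coupling and heterogeneity of the ring network."""

    N: int = 200
    g_stn_to_gpe: float = 0.4        # nS/um^2
    g_gpe_to_stn: float = 1.38       # nS/um^2
    v_stn_to_gpe: float = 0.0        # mV (excitatory reversal)
    v_gpe_to_stn: float = -100.0     # mV (inhibitory reversal)
    stn_synapse: SynapseParams = STN_SYNAPSE
    gpe_synapse: SynapseParams = GPE_SYNAPSE
    # heterogeneity: Gaussian (mean, sd); the sd values are the calibrated
    # spread that sustains the fluctuating partially synchronized baseline
    # (see docs/methods.md on why a sub-percent spread over-rigidifies it)
    stn_iapp_mean: float = 10.0      # pA/um^2
    stn_iapp_sd: float = 0.075
    gpe_eps_mean: float = 0.0055     # 1/ms
    gpe_eps_sd: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 3:
            raise ValueError("N must be at least 3 (GPe fan-out of 3)")
        if self.stn_iapp_sd < 0 or self.gpe_eps_sd < 0:
            raise ValueError("heterogeneity sd must be nonnegative")
        if self.g_stn_to_gpe < 0 or self.g_gpe_to_stn < 0:
            raise ValueError("synaptic weights must be nonnegative")

    def replace(self, **overrides) -> "NetworkConfig":
        return _dc_replace(self, **overrides)


@dataclass(frozen=True)
class Connectivity:
    """Edge structure of the ring: fixed fan-outs, periodic wrap."""

    N: int
    stn_to_gpe: np.ndarray     # (N,)   GPe target of each STN cell
    gpe_to_stn: np.ndarray     # (N, 3) STN targets of each GPe cell

    def edge_list(self):
        """All edges as (source population, source idx, target population,
        target idx) tuples, e.g. for CSV export."""
        edges = [("STN", j, "GPe", int(self.stn_to_gpe[j])) for j in range(self.N)]
        for j in range(self.N):
            for t in self.gpe_to_stn[j]:
                edges.append(("GPe", j, "STN", int(t)))
        return edges


def build_lattice(N: int) -> Connectivity:
    """Build the periodic 1-D lattice: STN j -> GPe j, GPe j -> STN {j-1,j,j+1}."""
    if N < 3:
        raise ValueError("N must be at least 3")
    idx = np.arange(N)
    stn_to_gpe = idx.copy()
    gpe_to_stn = np.stack([(idx - 1) % N, idx, (idx + 1) % N], axis=1)
    return Connectivity(N=N, stn_to_gpe=stn_to_gpe, gpe_to_stn=gpe_to_stn)


def synaptic_current(v_post: float, s_presum: float, g: float, v_rev: float) -> float:
    """Synaptic current ``g * (v_post - v_rev) * sum(s_pre)`` in pA/um^2."""
    if s_presum < 0:
        raise ValueError("presynaptic sum must be nonnegative")
    return g * (v_post - v_rev) * s_presum


def synapse_rhs(s: float, v_pre: float, syn: SynapseParams) -> float:
    """ds/dt of one synaptic gating variable given the presynaptic voltage."""
    h_inf = float(expit(((v_pre - syn.theta_g) - syn.theta_g_H) / syn.sigma_g_H))
    return syn.alpha * h_inf * (1.0 - s) - syn.beta * s


def sample_heterogeneity(cfg: NetworkConfig, seed: int) -> Tuple[np.ndarray, np.ndarray]:
    """Draw per-cell STN I_app and GPe eps vectors from the configured Gaussians.

    Deterministic for a fixed seed.  Returns ``(iapp_stn, eps_gpe)``,
    each of length ``cfg.N``.
    """
    if cfg.stn_iapp_sd < 0 or cfg.gpe_eps_sd < 0:
        raise ValueError("heterogeneity sd must be nonnegative")
    rng = np.random.default_rng(seed)
    iapp = rng.normal(cfg.stn_iapp_mean, cfg.stn_iapp_sd, size=cfg.N)
    eps = rng.normal(cfg.gpe_eps_mean, cfg.gpe_eps_sd, size=cfg.N)
    # calcium kinetics must stay well-posed even under extreme spreads
    np.clip(eps, 1e-6, None, out=eps)
    return iapp, eps
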