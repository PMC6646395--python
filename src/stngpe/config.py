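"""Configuration files, result serialization, run manifests and fixtures.

Configurations are human-readable YAML with nested sections (``network``,
``controller``, ``pulse``, ``cells``, ``sim``); physical quantities carry
units in their key names (``_ms``, ``_Hz``, ``_mV``).  Loading validates all
cross-field invariants (threshold ordering, pulse-geometry feasibility) and
fills defaults, so a loaded config is always runnable.  Every result can be
written together with a manifest (resolved config + package version + seeds)
that makes the run reproducible.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import warnings
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from .cells import CellParams, GPE_PARAMS, STN_PARAMS
from .engine import SimulationConfig, SimulationResult
from .network import NetworkConfig, SynapseParams
from .stimulation import (ControllerConfig, PulseTrainConfig,
                          max_charge_balanced_gap, monophasic_gap_threshold)

__all__ = ["load_config", "dump_config", "config_to_dict", "write_results",
           "read_summary", "make_fixture"]


class ConfigError(ValueError):
    """A configuration invariant is violated; names the offending field."""


# ---------------------------------------------------------------------------
# config <-> dict
# ---------------------------------------------------------------------------

_CTL_KEYS = {"mode": "mode", "K": "K", "tau_ms": "tau", "Th_on": "Th_on",
             "Th_off": "Th_off", "T_ramp_ms": "T_ramp"}
_PULSE_KEYS = {"F_Hz": "F", "PW_ms": "PW", "GW_ms": "GW", "ratio": "ratio"}
_SIM_KEYS = ("duration_ms", "stim_onset_ms", "dt_ms", "transient_skip_ms",
             "analysis_start_ms", "filter_period_ms", "filter_alpha_d",
             "filter_k_f", "spike_threshold_mV", "spike_refractory_ms",
             "isi_gap_ms", "r_grid_dt_ms", "record_stride", "ic_seed",
             "ic_mode")


def _cell_overrides(base: CellParams, overrides: Dict) -> CellParams:
    merged = {}
    for key, val in (overrides or {}).items():
        if not hasattr(base, key):
            raise ConfigError(f"unknown cell parameter {key!r}")
        current = getattr(base, key)
        if isinstance(current, dict):
            new = dict(current)
            new.update(val)
            merged[key] = new
        else:
            merged[key] = val
    return base.replace(**merged) if merged else base


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML run configuration.

    Raises :class:`ConfigError` naming the offending field on any violated
    invariant; warns when the interphase gap exceeds the charge-balanced
    limit (the run is still allowed, matching the physical pulse generator).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: Dict) -> SimulationConfig:
    net_raw = dict(raw.get("network", {}))
    for syn_key in ("stn_synapse", "gpe_synapse"):
        if syn_key in net_raw:
            net_raw[syn_key] = SynapseParams(**net_raw[syn_key])
    try:
        network = NetworkConfig(**net_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"network: {exc}") from exc

    ctl_raw = {_CTL_KEYS[k]: v for k, v in raw.get("controller", {}).items()
               if k in _CTL_KEYS}
    unknown = set(raw.get("controller", {})) - set(_CTL_KEYS)
    if unknown:
        raise ConfigError(f"controller: unknown keys {sorted(unknown)}")
    try:
        controller = ControllerConfig(**ctl_raw)
    except ValueError as exc:
        raise ConfigError(f"controller: {exc}") from exc

    pulse_raw = {_PULSE_KEYS[k]: v for k, v in raw.get("pulse", {}).items()
                 if k in _PULSE_KEYS}
    unknown = set(raw.get("pulse", {})) - set(_PULSE_KEYS)
    if unknown:
        raise ConfigError(f"pulse: unknown keys {sorted(unknown)}")
    try:
        pulse = PulseTrainConfig(**pulse_raw)
    except ValueError as exc:
        raise ConfigError(f"pulse: {exc}") from exc

    cells = raw.get("cells", {})
    stn = _cell_overrides(STN_PARAMS, cells.get("stn", {}))
    gpe = _cell_overrides(GPE_PARAMS, cells.get("gpe", {}))

    sim_raw = {k: v for k, v in raw.get("sim", {}).items() if k in _SIM_KEYS}
    unknown = set(raw.get("sim", {})) - set(_SIM_KEYS)
    if unknown:
        raise ConfigError(f"sim: unknown keys {sorted(unknown)}")
    try:
        cfg = SimulationConfig(network=network, controller=controller,
                               pulse=pulse, stn_params=stn, gpe_params=gpe,
                               **sim_raw)
    except ValueError as exc:
        raise ConfigError(f"sim: {exc}") from exc

    gap_limit = max_charge_balanced_gap(pulse.F, pulse.PW, pulse.ratio)
    if pulse.GW > monophasic_gap_threshold(pulse.F, pulse.PW):
        raise ConfigError(
            f"pulse.GW_ms: gap {pulse.GW} ms exceeds the monophasic limit "
            f"{monophasic_gap_threshold(pulse.F, pulse.PW):.2f} ms")
    if pulse.GW > gap_limit:
        warnings.warn(f"interphase gap {pulse.GW} ms exceeds the "
                      f"charge-balanced limit {gap_limit:.2f} ms; pulses are "
                      "no longer charge balanced", stacklevel=2)
    return cfg


def config_to_dict(cfg: SimulationConfig) -> Dict:
    """Full resolved configuration as a plain nested dict (YAML/JSON safe)."""
    net = dataclasses.asdict(cfg.network)
    ctl_inv = {v: k for k, v in _CTL_KEYS.items()}
    ctl = {ctl_inv[f.name]: getattr(cfg.controller, f.name)
           for f in dataclasses.fields(cfg.controller)}
    pulse_inv = {v: k for k, v in _PULSE_KEYS.items()}
    pulse = {pulse_inv[f.name]: getattr(cfg.pulse, f.name)
             for f in dataclasses.fields(cfg.pulse)}
    sim = {k: getattr(cfg, k) for k in _SIM_KEYS}
    out = {"network": net, "controller": ctl, "pulse": pulse,
           "cells": {"stn": dataclasses.asdict(cfg.stn_params),
                     "gpe": dataclasses.asdict(cfg.gpe_params)},
           "sim": sim}
    return json.loads(json.dumps(out, default=float))


def dump_config(cfg: SimulationConfig, path=None) -> str:
    """Serialize a config to YAML; optionally write it to ``path``."""
    text = yaml.safe_dump(config_to_dict(cfg), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_results(result: SimulationResult, outdir, stem: str = "run",
                  hdf5: bool = False) -> Dict[str, Path]:
    """Write time series (CSV or HDF5), summary JSON and a run manifest.

    Returns the mapping of artifact kind to path.  The summary JSON holds
    exactly ``result.summary`` so a round-trip read reproduces it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    frame = result.series_frame()
    if hdf5:
        import h5py

        series = outdir / f"{stem}_series.h5"
        with h5py.File(series, "w") as fh:
            for col in frame.columns:
                fh.create_dataset(col, data=frame[col].to_numpy())
            fh.create_dataset("spike_times_ms", data=result.spike_times)
            fh.create_dataset("spike_ids", data=result.spike_ids)
    else:
        series = outdir / f"{stem}_series.csv"
        frame.to_csv(series, index=False)
        spikes = outdir / f"{stem}_spikes.csv"
        pd.DataFrame({"t_ms": result.spike_times,
                      "neuron": result.spike_ids}).to_csv(spikes, index=False)
        paths["spikes"] = spikes
    paths["series"] = series

    summary = outdir / f"{stem}_summary.json"
    summary.write_text(json.dumps(result.summary, indent=2, default=float))
    paths["summary"] = summary

    from . import __version__

    manifest = outdir / f"{stem}_manifest.json"
    manifest.write_text(json.dumps({
        "package": "stngpe",
        "version": __version__,
        "created": datetime.datetime.now().isoformat(timespec="seconds"),
        "config": config_to_dict(result.config),
        "outputs": {k: str(v) for k, v in paths.items()},
    }, indent=2))
    paths["manifest"] = manifest
    return paths


def read_summary(path) -> Dict[str, float]:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, seed: int = 0, outdir: Optional[Path] = None):
    """Small deterministic fixtures for tests and demos.

    ``tiny-network``: a fast N=20 run configuration (seconds to simulate).
    ``synthetic-lfp``: a noisy ~10 Hz sinusoid resembling the raw LFP.
    ``synthetic-bursts``: an order-parameter-like trace with planted burst
    intervals plus the ground-truth intervals.

    Returns the fixture object; with ``outdir`` also writes files.
    """
    rng = np.random.default_rng(seed)
    if kind == "tiny-network":
        cfg = SimulationConfig(
            network=NetworkConfig(N=20, seed=seed),
            controller=ControllerConfig(mode="cDBS", K=0.0),
            duration_ms=2000.0, stim_onset_ms=1000.0,
            transient_skip_ms=500.0, ic_seed=seed + 1)
        if outdir is not None:
            dump_config(cfg, Path(outdir) / "tiny_network.yaml")
        return cfg
    if kind == "synthetic-lfp":
        dt = 0.1
        t = np.arange(0.0, 4000.0, dt)
        period = 103.0
        lfp = (0.02 * np.sin(2 * np.pi * t / period)
               + 0.002 * rng.standard_normal(t.size))
        if outdir is not None:
            pd.DataFrame({"t_ms": t, "lfp": lfp}).to_csv(
                Path(outdir) / "synthetic_lfp.csv", index=False)
        return t, lfp
    if kind == "synthetic-bursts":
        dt = 10.0               # ms, matches the burst-analysis grid
        t = np.arange(0.0, 120_000.0, dt)
        base = 0.15 + 0.01 * rng.standard_normal(t.size)
        intervals = []
        t0 = 8000.0
        while t0 < t[-1] - 20_000.0:
            length = float(rng.uniform(2000.0, 12_000.0))
            intervals.append((t0, t0 + length))
            base[(t >= t0) & (t < t0 + length)] += 0.4
            t0 += length + float(rng.uniform(6000.0, 15_000.0))
        if outdir is not None:
            outdir = Path(outdir)
            pd.DataFrame({"t_ms": t, "R": base}).to_csv(
                outdir / "synthetic_bursts.csv", index=False)
            (outdir / "synthetic_bursts_truth.json").write_text(
                json.dumps({"intervals_ms": intervals}))
        return t, base, intervals
    raise ValueError(f"unknown fixture kind {kind!r}")
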