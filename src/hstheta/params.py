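"""Parameter-file loading, validation and construction of cell models.

The whole model is configuration: one YAML file defines gating kinetics,
per-class channel tables, population sizes and drives, synapse kinetics and
the projection list.  ``default_parameters()`` returns the shipped control
condition; experiment conditions are derived from it by scaling entries
(see :mod:`hstheta.experiments`).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from functools import lru_cache

import yaml

from .channels import (
    ChannelSpec,
    ConfigurationError,
    GateKinetics,
    RateFunction,
)
from .neurons import NeuronModel

__all__ = [
    "default_parameters",
    "load_parameters",
    "validate_parameters",
    "build_gate_kinetics",
    "build_cell",
    "CELL_CLASSES",
]

CELL_CLASSES = ("pyramidal", "basket", "olm", "msgaba")

_TOP_KEYS = {"simulation", "populations", "kinetics", "cells", "synapses", "projections"}
_SIM_KEYS = {
    "dt_ms", "duration_ms", "transient_discard_ms", "noise_sd_mv", "noise_tau_ms",
    "record_dt_ms", "spike_threshold_mv", "spike_min_separation_ms",
}
_POP_KEYS = {"n", "mu_i", "sigma_i"}
_KIN_KEYS = {"form", "phi", "alpha", "beta", "vh", "k", "tau0", "tau_amp", "tau_vh", "tau_k"}
_RATE_KEYS = {"kind", "a", "vh", "k"}
_CELL_KEYS = {"cm", "g_c", "p_soma", "soma", "dendrite", "pools"}
_CHAN_KEYS = {"g_max", "e_rev", "gates", "ca_pool", "ca_kd"}
_POOL_KEYS = {"b", "tau_ca", "k_unit"}
_SYN_KEYS = {"e_rev", "tau_rise", "tau_decay", "voltage_dependence"}
_PROJ_KEYS = {"source", "target", "compartment", "transmitter", "g_max", "in_degree",
              "tau_rise", "tau_decay"}

_REQUIRED_SOMA = {
    "pyramidal": {"na", "k", "leak", "ca", "h", "a"},
    "basket": {"na", "k", "leak"},
    "olm": {"na", "k", "leak", "ca", "h", "ahp"},
    "msgaba": {"na", "k", "leak", "ks"},
}
_REQUIRED_DEND = {"leak", "ca", "h", "ahp", "ct"}


def _check_keys(mapping, allowed, where):
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(f"unknown keys {sorted(unknown)} in {where}")


@lru_cache(maxsize=1)
def _default_raw() -> str:
    ref = importlib.resources.files("hstheta") / "config" / "default.yaml"
    return ref.read_text()


def default_parameters() -> dict:
    """Deep copy of the shipped control parameter set."""
    params = yaml.safe_load(_default_raw())
    validate_parameters(params)
    return params


def load_parameters(path) -> dict:
    """Load and validate a parameter file."""
    with open(path) as fh:
        params = yaml.safe_load(fh)
    validate_parameters(params)
    return params


def validate_parameters(params: dict) -> None:
    """Schema check: unknown keys rejected, referenced names must exist."""
    if not isinstance(params, dict):
        raise ConfigurationError("parameter file must be a mapping")
    _check_keys(params, _TOP_KEYS, "top level")
    for key in _TOP_KEYS:
        if key not in params:
            raise ConfigurationError(f"missing section {key!r}")
    _check_keys(params["simulation"], _SIM_KEYS, "simulation")
    for pop, spec in params["populations"].items():
        if pop not in CELL_CLASSES:
            raise ConfigurationError(f"unknown population {pop!r}")
        _check_keys(spec, _POP_KEYS, f"populations.{pop}")
        if spec["n"] < 0 or spec["sigma_i"] < 0:
            raise ConfigurationError(f"populations.{pop}: n >= 0 and sigma_i >= 0")
    for name, kin in params["kinetics"].items():
        _check_keys(kin, _KIN_KEYS, f"kinetics.{name}")
        if kin["form"] not in ("alpha_beta", "inf_tau"):
            raise ConfigurationError(f"kinetics.{name}: bad form {kin['form']!r}")
        for rate in ("alpha", "beta"):
            if rate in kin:
                _check_keys(kin[rate], _RATE_KEYS, f"kinetics.{name}.{rate}")
    for cls, cell in params["cells"].items():
        if cls not in CELL_CLASSES:
            raise ConfigurationError(f"unknown cell class {cls!r}")
        _check_keys(cell, _CELL_KEYS, f"cells.{cls}")
        comps = ["soma"] + (["dendrite"] if "dendrite" in cell else [])
        if cls == "pyramidal" and "dendrite" not in cell:
            raise ConfigurationError("pyramidal cell requires a dendrite compartment")
        if cls == "pyramidal" and not (0.0 < cell.get("p_soma", 0.5) < 1.0):
            raise ConfigurationError("p_soma must lie in (0, 1)")
        for comp in comps:
            chans = cell[comp]["channels"]
            for cname, chan in chans.items():
                _check_keys(chan, _CHAN_KEYS, f"cells.{cls}.{comp}.{cname}")
                for g in chan.get("gates", []):
                    if g["gate"] not in params["kinetics"]:
                        raise ConfigurationError(
                            f"cells.{cls}.{comp}.{cname}: unknown gate {g['gate']!r}")
                if "ca_pool" in chan:
                    if g_pool := chan["ca_pool"]:
                        if g_pool not in cell.get("pools", {}):
                            raise ConfigurationError(
                                f"cells.{cls}.{comp}.{cname}: unknown ca pool {g_pool!r}")
        missing = _REQUIRED_SOMA[cls] - set(cell["soma"]["channels"])
        if missing:
            raise ConfigurationError(f"cells.{cls}.soma missing channels {sorted(missing)}")
        if cls == "pyramidal":
            missing = _REQUIRED_DEND - set(cell["dendrite"]["channels"])
            if missing:
                raise ConfigurationError(
                    f"cells.pyramidal.dendrite missing channels {sorted(missing)}")
        for pname, pool in cell.get("pools", {}).items():
            _check_keys(pool, _POOL_KEYS, f"cells.{cls}.pools.{pname}")
    for name, syn in params["synapses"].items():
        _check_keys(syn, _SYN_KEYS, f"synapses.{name}")
        if not (syn["tau_decay"] > syn["tau_rise"] > 0):
            raise ConfigurationError(f"synapses.{name}: need tau_decay > tau_rise > 0")
    for i, proj in enumerate(params["projections"]):
        _check_keys(proj, _PROJ_KEYS, f"projections[{i}]")
        if proj["transmitter"] not in params["synapses"]:
            raise ConfigurationError(f"projections[{i}]: unknown transmitter")
        if proj["source"] not in CELL_CLASSES or proj["target"] not in CELL_CLASSES:
            raise ConfigurationError(f"projections[{i}]: unknown population")
        # transmitter-type rules of the network architecture
        src, tgt, tx = proj["source"], proj["target"], proj["transmitter"]
        if src == "pyramidal":
            ok = (tgt, tx) in {("basket", "ampa"), ("olm", "ampa"), ("olm", "nmda")}
        else:
            ok = tx == "gaba_a"
        if not ok:
            raise ConfigurationError(
                f"projections[{i}]: {src}->{tgt} via {tx} violates the "
                "transmitter rules (pyramidal->basket AMPA, pyramidal->OLM "
                "AMPA+NMDA, all others GABA_A)")


def build_gate_kinetics(params: dict, name: str) -> GateKinetics:
    """Construct a :class:`GateKinetics` (exponent 1) from its config entry."""
    try:
        kin = params["kinetics"][name]
    except KeyError:
        raise ConfigurationError(f"no kinetics entry {name!r}") from None
    kwargs = dict(gate_name=name, form=kin["form"], phi=kin.get("phi", 1.0))
    if kin["form"] == "alpha_beta":
        kwargs["alpha"] = RateFunction(**kin["alpha"])
        kwargs["beta"] = RateFunction(**kin["beta"])
    else:
        kwargs.update(
            vh=kin["vh"], k=kin["k"], tau0=kin.get("tau0", 1.0),
            tau_amp=kin.get("tau_amp", 0.0), tau_vh=kin.get("tau_vh", 0.0),
            tau_k=kin.get("tau_k", 1.0),
        )
    return GateKinetics(**kwargs)


def _build_channel(params: dict, name: str, chan: dict) -> ChannelSpec:
    gates = tuple(
        _with_exponent(build_gate_kinetics(params, g["gate"]), g.get("exponent", 1))
        for g in chan.get("gates", [])
    )
    return ChannelSpec(
        name=name, g_max=chan["g_max"], e_rev=chan["e_rev"], gates=gates,
        ca_pool=chan.get("ca_pool"), ca_kd=chan.get("ca_kd", 1.0),
    )


def _with_exponent(gk: GateKinetics, exponent: int) -> GateKinetics:
    return dataclasses.replace(gk, exponent=exponent)


def build_cell(params: dict, cell_class: str) -> NeuronModel:
    """Assemble the :class:`NeuronModel` for one cell class."""
    cell = params["cells"][cell_class]
    compartments = {}
    for comp in ("soma", "dendrite"):
        if comp in cell:
            compartments[comp] = tuple(
                _build_channel(params, name, chan)
                for name, chan in cell[comp]["channels"].items()
            )
    return NeuronModel(
        cell_class=cell_class,
        compartments=compartments,
        cm=cell["cm"],
        g_c=cell.get("g_c", 0.0),
        p_soma=cell.get("p_soma", 1.0),
        pools={name: dict(pool) for name, pool in cell.get("pools", {}).items()},
    )
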