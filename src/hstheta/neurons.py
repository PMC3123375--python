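"""Cell models: compartments, membrane equations, single-cell integration.

A :class:`NeuronModel` is a cell class (pyramidal, basket, OLM or MSGABA) as
a set of compartments, each carrying a channel tuple.  Pyramidal cells have
two compartments (soma, dendrite) electrically coupled through g_c with
somatic area fraction p; the other classes are one-compartment.

The derivative function here is the plain reference path — dictionaries and
per-channel calls — used for unit tests and for adaptive-step cross-checks
of the vectorized network kernel.  Network-scale integration lives in
:mod:`hstheta.engine`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .channels import (
    CalciumPool,
    ChannelSpec,
    CompartmentState,
    ConfigurationError,
    calcium_pool_step,
    channel_conductance,
    channel_current,
    gate_steady_state_and_tau,
)

__all__ = ["NeuronModel", "membrane_derivatives", "initial_state", "integrate_neuron"]


@dataclass(frozen=True)
class NeuronModel:
    """A cell class as a set of compartments plus electrical parameters."""

    cell_class: str
    compartments: dict[str, tuple[ChannelSpec, ...]]
    cm: float  # µF/cm²
    g_c: float = 0.0  # mS/cm², soma-dendrite coupling (pyramidal)
    p_soma: float = 1.0  # somatic area fraction (pyramidal)
    pools: dict[str, dict] = field(default_factory=dict)

    @property
    def is_two_compartment(self) -> bool:
        return "dendrite" in self.compartments

    def gates_of(self, comp: str):
        seen = {}
        for chan in self.compartments[comp]:
            for gate in chan.gates:
                seen.setdefault(gate.gate_name, gate)
        return seen


def initial_state(model: NeuronModel, v0: float = -65.0) -> dict[str, CompartmentState]:
    """Rest-like initial state: V = v0, gates at steady state, pools empty."""
    states = {}
    for comp in model.compartments:
        gate_values = {}
        for name, gate in model.gates_of(comp).items():
            x_inf, _ = gate_steady_state_and_tau(gate, v0)
            gate_values[name] = x_inf
        pools = {
            label: CalciumPool(label=label, **cfg) for label, cfg in model.pools.items()
        }
        states[comp] = CompartmentState(v=v0, gate_values=gate_values, pools=pools)
    return states


def membrane_derivatives(
    model: NeuronModel,
    states: dict[str, CompartmentState],
    i_drive: float = 0.0,
    i_syn: dict[str, float] | None = None,
) -> dict[str, dict[str, float]]:
    """Time derivatives of all membrane state variables.

    Soma:      C_m dV_s/dt = −ΣI_chan,s + (g_c/p)(V_d−V_s) + I_drive + I_syn,s
    Dendrite:  C_m dV_d/dt = −ΣI_chan,d + (g_c/(1−p))(V_s−V_d) + I_syn,d
    Gates:     dx/dt = (x_inf − x)/tau_x
    Pools:     d[Ca]/dt = −B·k·I_Ca − [Ca]/tau_ca

    ``i_syn`` maps compartment name to the synaptic term already expressed
    as an *added* current (inward positive).  Raises on non-finite results.
    """
    i_syn = i_syn or {}
    if set(states) != set(model.compartments):
        raise ConfigurationError("state compartments do not match the model")
    derivs: dict[str, dict[str, float]] = {}
    for comp, chans in model.compartments.items():
        st = states[comp]
        i_total = sum(channel_current(c, st) for c in chans)
        dv = -i_total + i_syn.get(comp, 0.0)
        if model.is_two_compartment:
            if comp == "soma":
                other = states["dendrite"].v
                dv += (model.g_c / model.p_soma) * (other - st.v)
            else:
                other = states["soma"].v
                dv += (model.g_c / (1.0 - model.p_soma)) * (other - st.v)
        if comp == "soma":
            dv += i_drive
        out = {"v": dv / model.cm}
        for name, gate in model.gates_of(comp).items():
            x_inf, tau = gate_steady_state_and_tau(gate, st.v)
            out[name] = (x_inf - st.gate_values[name]) / tau
        for label, pool in st.pools.items():
            i_ca = sum(
                channel_current(c, st) for c in chans if c.name == "ca"
            )
            out[f"ca_{label}"] = -pool.b * pool.k_unit * i_ca - pool.conc / pool.tau_ca
        if not all(math.isfinite(v) for v in out.values()):
            raise FloatingPointError(
                f"non-finite derivative in {model.cell_class}/{comp}: {out}"
            )
        derivs[comp] = out
    return derivs


def integrate_neuron(
    model: NeuronModel,
    i_drive: float,
    duration: float,
    dt: float = 0.05,
    v0: float = -65.0,
    record_every: int = 1,
):
    """Fixed-step integration of an isolated neuron (reference path).

    Exponential-Euler updates for the membrane potential (conductances
    frozen over the step), gates and calcium pools — the same scheme as the
    network kernel.  Returns ``(t, traces)`` with per-compartment voltages.
    """
    states = initial_state(model, v0)
    n_steps = int(round(duration / dt))
    comps = list(model.compartments)
    n_rec = n_steps // record_every + 1
    t = np.arange(n_rec) * dt * record_every
    traces = {c: np.empty(n_rec) for c in comps}
    for c in comps:
        traces[c][0] = states[c].v
    k = 1
    for step in range(1, n_steps + 1):
        dv = {}
        for comp in comps:
            st = states[comp]
            chans = model.compartments[comp]
            g_sum = 0.0
            src = 0.0
            for c in chans:
                g = channel_conductance(c, st)
                g_sum += g
                src += g * c.e_rev
            if model.is_two_compartment:
                if comp == "soma":
                    g_c = model.g_c / model.p_soma
                    other = states["dendrite"].v
                else:
                    g_c = model.g_c / (1.0 - model.p_soma)
                    other = states["soma"].v
                g_sum += g_c
                src += g_c * other
            if comp == "soma":
                src += i_drive
            v_inf = src / g_sum
            dv[comp] = (
                v_inf + (st.v - v_inf) * math.exp(-dt * g_sum / model.cm)
            ) - st.v
        for comp in comps:
            st = states[comp]
            chans = model.compartments[comp]
            i_ca = sum(channel_current(c, st) for c in chans if c.name == "ca")
            v_old = st.v
            st.v += dv[comp]
            for name, gate in model.gates_of(comp).items():
                x_inf, tau = gate_steady_state_and_tau(gate, v_old)
                x = st.gate_values[name]
                x = x_inf + (x - x_inf) * math.exp(-dt / tau)
                st.gate_values[name] = min(max(x, 0.0), 1.0)
            for label in list(st.pools):
                st.pools[label] = calcium_pool_step(st.pools[label], i_ca, dt)
        if step % record_every == 0:
            for c in comps:
                traces[c][k] = states[c].v
            k += 1
    return t, traces
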