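"""Voltage- and calcium-gated channel machinery for conductance-based neurons.

Everything downstream (cell models, the network kernel) is built from three
primitives defined here:

* :class:`GateKinetics` — one Hodgkin–Huxley gating variable, given either as
  an alpha/beta rate pair or as an explicit steady-state/time-constant pair.
* :class:`ChannelSpec` — a conductance: maximal density, reversal potential,
  a product of gates, and (for Ca-activated K channels) a calcium pool whose
  concentration enters the activation as ``[Ca]/([Ca]+Kd)``.
* :class:`CalciumPool` — a first-order intracellular calcium buffer fed by a
  fraction ``B`` of the calcium current.

Units: mV, ms, mS/cm², µA/cm²; calcium concentration is in the arbitrary
units of the source cell models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ConfigurationError",
    "RateFunction",
    "GateKinetics",
    "ChannelSpec",
    "CalciumPool",
    "CompartmentState",
    "gate_steady_state_and_tau",
    "channel_current",
    "channel_conductance",
    "calcium_pool_step",
    "V_RANGE",
]

#: voltage range (mV) over which kinetics are expected to be well behaved
V_RANGE = (-120.0, 60.0)


class ConfigurationError(ValueError):
    """A channel/neuron definition references something that does not exist."""


@dataclass(frozen=True)
class RateFunction:
    """A parametric voltage-dependent rate (1/ms).

    kind:
        ``linoid``      a·(V−vh) / (1 − exp(−(V−vh)/k))
        ``exponential`` a·exp((V−vh)/k)
        ``sigmoid``     a / (1 + exp(−(V−vh)/k))

    The linoid form has a removable singularity at ``V == vh``; it is
    evaluated by series expansion in a narrow window around that point.
    """

    kind: str
    a: float
    vh: float
    k: float

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        u = (v - self.vh) / self.k
        if self.kind == "linoid":
            # a*k*u/(1-exp(-u)); series a*k*(1 + u/2 + u^2/12) near u=0
            with np.errstate(over="ignore"):
                dens = -np.expm1(-u)
            small = np.abs(dens) < 1e-6
            safe = np.where(small, 1.0, dens)
            out = self.a * self.k * np.where(
                small, 1.0 + u / 2.0 + u * u / 12.0, u / safe
            )
        elif self.kind == "exponential":
            out = self.a * np.exp(u)
        elif self.kind == "sigmoid":
            out = self.a / (1.0 + np.exp(-u))
        else:  # pragma: no cover - guarded at construction time by loaders
            raise ConfigurationError(f"unknown rate kind {self.kind!r}")
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GateKinetics:
    """One gating variable ``x`` with dynamics dx/dt = (x_inf − x)/tau_x.

    ``form == "alpha_beta"``: x_inf = α/(α+β), tau = 1/(φ·(α+β)).
    ``form == "inf_tau"``:    x_inf = 1/(1+exp(−(V−vh)/k)) and
    tau(V) = (tau0 + tau_amp·sech((V−tau_vh)/tau_k)) / φ.

    ``exponent`` is the power of the gate in the conductance product; ``phi``
    is a temperature-like rate scale.
    """

    gate_name: str
    form: str
    exponent: int = 1
    phi: float = 1.0
    alpha: RateFunction | None = None
    beta: RateFunction | None = None
    vh: float = 0.0
    k: float = 1.0
    tau0: float = 1.0
    tau_amp: float = 0.0
    tau_vh: float = 0.0
    tau_k: float = 1.0

    def steady_state(self, v):
        if self.form == "alpha_beta":
            a, b = self.alpha(v), self.beta(v)
            return a / (a + b)
        v = np.asarray(v, dtype=float)
        out = 1.0 / (1.0 + np.exp(-(v - self.vh) / self.k))
        return float(out) if out.ndim == 0 else out

    def time_constant(self, v):
        if self.form == "alpha_beta":
            a, b = self.alpha(v), self.beta(v)
            return 1.0 / (self.phi * (a + b))
        v = np.asarray(v, dtype=float)
        tau = self.tau0 + self.tau_amp / np.cosh((v - self.tau_vh) / self.tau_k)
        out = tau / self.phi
        return float(out) if out.ndim == 0 else out


def gate_steady_state_and_tau(kinetics: GateKinetics, v):
    """Evaluate (x_inf, tau_x) of a gate at membrane potential ``v`` (mV)."""
    x_inf = kinetics.steady_state(v)
    tau = kinetics.time_constant(v)
    if not np.all(np.isfinite(x_inf)) or not np.all(np.isfinite(tau)):
        raise FloatingPointError(
            f"non-finite kinetics for gate {kinetics.gate_name!r} at V={v!r}"
        )
    return x_inf, tau


@dataclass
class CalciumPool:
    """First-order calcium buffer: d[Ca]/dt = −B·k·I_Ca − [Ca]/tau_ca.

    ``b`` is the fraction of the Ca²⁺ influx feeding the pool (the knob the
    BK-channel experiments scale), ``k_unit`` a fixed unit-conversion
    constant, ``tau_ca`` the removal time constant (ms).  Inward calcium
    current is negative by convention, so −B·k·I_Ca is a source term.
    """

    label: str
    b: float = 1.0
    tau_ca: float = 80.0
    k_unit: float = 0.13
    conc: float = 0.0

    def __post_init__(self):
        if self.b < 0 or self.tau_ca <= 0:
            raise ConfigurationError("calcium pool requires b >= 0, tau_ca > 0")


def calcium_pool_step(pool: CalciumPool, i_ca: float, dt: float) -> CalciumPool:
    """Advance a calcium pool by ``dt`` ms under calcium current ``i_ca``.

    Uses the exact update for the linear ODE with ``i_ca`` held over the
    step, so pure decay (i_ca = 0) is reproduced to machine precision.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    decay = math.exp(-dt / pool.tau_ca)
    source = -pool.b * pool.k_unit * i_ca * pool.tau_ca  # steady state of conc
    conc = pool.conc * decay + source * (1.0 - decay)
    return replace(pool, conc=max(conc, 0.0))


@dataclass(frozen=True)
class ChannelSpec:
    """One membrane conductance.

    ``gates`` multiply as ``Π x_i^{e_i}``; if ``ca_pool`` is set (AHP, CT
    channels) the activation is additionally multiplied by
    ``[Ca]/([Ca]+ca_kd)`` evaluated on the referenced pool.
    """

    name: str
    g_max: float
    e_rev: float
    gates: tuple[GateKinetics, ...] = ()
    ca_pool: str | None = None
    ca_kd: float = 1.0

    def __post_init__(self):
        if self.g_max < 0:
            raise ConfigurationError(f"channel {self.name!r}: g_max must be >= 0")
        if self.name == "leak" and self.gates:
            raise ConfigurationError("leak channel carries no gates")


@dataclass
class CompartmentState:
    """Membrane state of one compartment: V, gate values, calcium pools."""

    v: float
    gate_values: dict[str, float] = field(default_factory=dict)
    pools: dict[str, CalciumPool] = field(default_factory=dict)


def channel_conductance(spec: ChannelSpec, state: CompartmentState) -> float:
    """Instantaneous conductance g_max · Π gateᵉ (· Ca activation) in mS/cm²."""
    act = 1.0
    for gate in spec.gates:
        try:
            x = state.gate_values[gate.gate_name]
        except KeyError:
            raise ConfigurationError(
                f"channel {spec.name!r} needs gate {gate.gate_name!r} "
                "absent from compartment state"
            ) from None
        act *= x ** gate.exponent
    if spec.ca_pool is not None:
        try:
            conc = state.pools[spec.ca_pool].conc
        except KeyError:
            raise ConfigurationError(
                f"channel {spec.name!r} references missing calcium pool "
                f"{spec.ca_pool!r}"
            ) from None
        act *= conc / (conc + spec.ca_kd)
    return spec.g_max * act


def channel_current(spec: ChannelSpec, state: CompartmentState) -> float:
    """Current density (µA/cm²) through ``spec`` given a compartment state.

    Outward current is positive: I = g_max · act · (V − E_rev).
    """
    act = 1.0
    for gate in spec.gates:
        try:
            x = state.gate_values[gate.gate_name]
        except KeyError:
            raise ConfigurationError(
                f"channel {spec.name!r} needs gate {gate.gate_name!r} "
                "absent from compartment state"
            ) from None
        act *= x ** gate.exponent
    if spec.ca_pool is not None:
        try:
            conc = state.pools[spec.ca_pool].conc
        except KeyError:
            raise ConfigurationError(
                f"channel {spec.name!r} references missing calcium pool "
                f"{spec.ca_pool!r}"
            ) from None
        act *= conc / (conc + spec.ca_kd)
    return spec.g_max * act * (state.v - spec.e_rev)
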