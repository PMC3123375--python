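"""Population construction, heterogeneous drive, and the sparse connectome.

The network has four populations (pyramidal, basket, OLM, medial-septal
GABAergic) wired by transmitter-typed projections: pyramidal cells excite
basket cells via AMPA and OLM cells via AMPA+NMDA; every other projection is
GABA_A.  Coupling is sparse and random with a fixed per-target in-degree,
realizing the "fixed average number of presynaptic inputs" constraint
exactly.  Per-neuron DC drives are Gaussian, redrawn per trial to emulate
tissue heterogeneity across simulated patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .channels import ConfigurationError

__all__ = [
    "PopulationSpec",
    "SynapseSpec",
    "Projection",
    "Connectome",
    "draw_heterogeneous_drive",
    "sample_connectome",
    "DualExpGating",
    "synaptic_gating_step",
    "synaptic_current",
    "nmda_unblock",
    "dual_exp_peak_time",
    "dual_exp_norm",
    "projections_from_params",
    "populations_from_params",
    "export_edge_list",
    "import_edge_list",
]


@dataclass(frozen=True)
class PopulationSpec:
    cell_class: str
    n: int
    mu_i: float  # mean DC drive, µA/cm²
    sigma_i: float  # drive SD, µA/cm²

    def __post_init__(self):
        if self.n < 0 or self.sigma_i < 0:
            raise ConfigurationError("population requires n >= 0 and sigma_i >= 0")


@dataclass(frozen=True)
class SynapseSpec:
    transmitter: str  # 'ampa' | 'nmda' | 'gaba_a'
    g_max: float
    e_rev: float
    tau_rise: float
    tau_decay: float
    voltage_dependence: bool = False  # NMDA magnesium block

    def __post_init__(self):
        if not (self.tau_decay > self.tau_rise > 0):
            raise ConfigurationError("need tau_decay > tau_rise > 0")
        if self.transmitter == "gaba_a" and self.e_rev >= -60.0:
            raise ConfigurationError("GABA_A reversal must lie below -60 mV")
        if self.transmitter in ("ampa", "nmda") and abs(self.e_rev) > 10.0:
            raise ConfigurationError("AMPA/NMDA reversal must be near 0 mV")


@dataclass(frozen=True)
class Projection:
    source: str
    target: str
    synapse: SynapseSpec
    in_degree: int
    target_compartment: str = "soma"  # pyramidal targets distinguish soma/dendrite

    def __post_init__(self):
        src, tgt, tx = self.source, self.target, self.synapse.transmitter
        if src == "pyramidal":
            ok = (tgt, tx) in {("basket", "ampa"), ("olm", "ampa"), ("olm", "nmda")}
        else:
            ok = tx == "gaba_a"
        if not ok:
            raise ConfigurationError(
                f"{src}->{tgt} via {tx} violates the transmitter rules")


@dataclass
class Connectome:
    """Per-projection adjacency: ``pre[projection][target, j]`` source index."""

    projections: tuple[Projection, ...]
    pre: list[np.ndarray]  # each (n_target, in_degree) int array
    seed: int

    def audit(self, pop_sizes: dict[str, int]) -> None:
        """Assert structural invariants: degrees, bounds, no self-connections."""
        for proj, pre in zip(self.projections, self.pre):
            n_src = pop_sizes[proj.source]
            n_tgt = pop_sizes[proj.target]
            assert pre.shape == (n_tgt, proj.in_degree)
            if pre.size:
                assert pre.min() >= 0 and pre.max() < n_src
            if proj.source == proj.target:
                tgt_idx = np.arange(n_tgt)[:, None]
                assert not np.any(pre == tgt_idx), "self-connection found"
            for row in pre:
                assert len(set(row.tolist())) == len(row), "duplicate presynaptic partner"


def draw_heterogeneous_drive(spec: PopulationSpec, seed: int) -> np.ndarray:
    """Per-neuron Gaussian DC drives (µA/cm²), reproducible under the seed."""
    rng = np.random.default_rng(seed)
    return rng.normal(spec.mu_i, spec.sigma_i, size=spec.n)


def sample_connectome(
    projections: list[Projection], pop_sizes: dict[str, int], seed: int
) -> Connectome:
    """Draw each target's presynaptic partners uniformly without replacement.

    Self-connections are excluded for within-population projections; the
    requested in-degree must not exceed the number of available sources.
    """
    rng = np.random.default_rng(seed)
    pre_lists = []
    for proj in projections:
        n_src = pop_sizes[proj.source]
        n_tgt = pop_sizes[proj.target]
        recurrent = proj.source == proj.target
        avail = n_src - 1 if recurrent else n_src
        if proj.in_degree > avail:
            raise ConfigurationError(
                f"{proj.source}->{proj.target}: in-degree {proj.in_degree} "
                f"exceeds {avail} available sources")
        pre = np.empty((n_tgt, proj.in_degree), dtype=np.int64)
        for t in range(n_tgt):
            pool = np.arange(n_src)
            if recurrent:
                pool = np.delete(pool, t)
            pre[t] = rng.choice(pool, size=proj.in_degree, replace=False)
        pre_lists.append(pre)
    return Connectome(tuple(projections), pre_lists, seed)


# --- synaptic kinetics ----------------------------------------------------
#
# Dual-exponential gating realized as the difference of two exponentials,
# s(t) = norm * (u - v) with du/dt = -u/tau_decay, dv/dt = -v/tau_rise and
# u,v incremented by 1 per presynaptic spike.  norm is chosen so a single
# spike yields a unit peak.


def dual_exp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Peak time of the dual-exponential kernel after a single spike."""
    return (
        tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    )


def dual_exp_norm(tau_rise: float, tau_decay: float) -> float:
    tp = dual_exp_peak_time(tau_rise, tau_decay)
    return 1.0 / (math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise))


@dataclass
class DualExpGating:
    """State of one lumped postsynaptic gating process."""

    spec: SynapseSpec
    u: float = 0.0
    v: float = 0.0

    @property
    def s(self) -> float:
        return dual_exp_norm(self.spec.tau_rise, self.spec.tau_decay) * (self.u - self.v)


def synaptic_gating_step(
    gating: DualExpGating, n_spikes: int, dt: float
) -> DualExpGating:
    """Advance the gating by dt (ms); ``n_spikes`` presynaptic spikes arrive.

    Decay is exact (exponential update); increments are applied after the
    decay so a spike at time t contributes its full kernel from t onward.
    """
    spec = gating.spec
    u = gating.u * math.exp(-dt / spec.tau_decay) + n_spikes
    v = gating.v * math.exp(-dt / spec.tau_rise) + n_spikes
    return DualExpGating(spec=spec, u=u, v=v)


def nmda_unblock(v_post: float):
    """Magnesium-block relief factor for NMDA receptors (Jahr–Stevens form)."""
    return 1.0 / (1.0 + 0.28 * np.exp(-0.062 * np.asarray(v_post, dtype=float)))


def synaptic_current(s: float, spec: SynapseSpec, v_post: float) -> float:
    """Postsynaptic current g_max·s·(V−E_rev), outward positive.

    NMDA receptors are additionally scaled by the voltage-dependent
    magnesium unblock factor evaluated at the current membrane potential.
    """
    i = spec.g_max * s * (v_post - spec.e_rev)
    if spec.voltage_dependence:
        i *= float(nmda_unblock(v_post))
    return i


# --- config plumbing ------------------------------------------------------


def populations_from_params(params: dict) -> dict[str, PopulationSpec]:
    return {
        name: PopulationSpec(name, cfg["n"], cfg["mu_i"], cfg["sigma_i"])
        for name, cfg in params["populations"].items()
    }


def projections_from_params(params: dict) -> list[Projection]:
    projs = []
    for cfg in params["projections"]:
        base = params["synapses"][cfg["transmitter"]]
        spec = SynapseSpec(
            transmitter=cfg["transmitter"],
            g_max=cfg["g_max"],
            e_rev=base["e_rev"],
            tau_rise=cfg.get("tau_rise", base["tau_rise"]),
            tau_decay=cfg.get("tau_decay", base["tau_decay"]),
            voltage_dependence=base.get("voltage_dependence", False),
        )
        projs.append(
            Projection(
                source=cfg["source"],
                target=cfg["target"],
                synapse=spec,
                in_degree=cfg["in_degree"],
                target_compartment=cfg.get("compartment", "soma"),
            )
        )
    return projs


def export_edge_list(connectome: Connectome, path) -> None:
    """Write the adjacency as text: source_pop source_idx target_pop target_idx transmitter."""
    with open(path, "w") as fh:
        fh.write("# source_pop\tsource_idx\ttarget_pop\ttarget_idx\ttransmitter\n")
        for proj, pre in zip(connectome.projections, connectome.pre):
            for t, row in enumerate(pre):
                for s in row:
                    fh.write(
                        f"{proj.source}\t{int(s)}\t{proj.target}\t{t}\t"
                        f"{proj.synapse.transmitter}\n"
                    )


def import_edge_list(path, projections: list[Projection], pop_sizes: dict[str, int]) -> Connectome:
    """Rebuild a connectome from an edge-list file for exact replay."""
    edges: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            sp, si, tp, ti, tx = line.split()
            edges.setdefault((sp, tp, tx), []).append((int(si), int(ti)))
    pre_lists = []
    for proj in projections:
        key = (proj.source, proj.target, proj.synapse.transmitter)
        pairs = edges.get(key, [])
        n_tgt = pop_sizes[proj.target]
        rows: list[list[int]] = [[] for _ in range(n_tgt)]
        for s, t in pairs:
            rows[t].append(s)
        pre = np.array([sorted(r) for r in rows], dtype=np.int64).reshape(
            n_tgt, proj.in_degree
        )
        pre_lists.append(pre)
    return Connectome(tuple(projections), pre_lists, seed=-1)
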