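"""Trial integration: seeds, noise, recording, and the kernel interface.

One *trial* is a seeded 10-s integration of the full network with
Ornstein-Uhlenbeck membrane noise.  Each trial represents one simulated
patient: heterogeneous drives and the sparse connectome are redrawn with
trial-indexed seeds, so trials are statistically independent realizations of
the same parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel as K
from .channels import ConfigurationError
from .network import (
    Connectome,
    draw_heterogeneous_drive,
    dual_exp_norm,
    populations_from_params,
    projections_from_params,
    sample_connectome,
)
from .params import build_gate_kinetics

__all__ = [
    "SimulationConfig",
    "TrialRecording",
    "SimulationFault",
    "integrate_trial",
    "run_trials",
    "detect_spikes",
    "trial_seeds",
    "save_recording",
    "load_recording",
    "export_raster",
]

POP_ORDER = ("pyramidal", "basket", "olm", "msgaba")
_POP_CODE = {name: i for i, name in enumerate(POP_ORDER)}


class SimulationFault(RuntimeError):
    """Numerical fault during integration, with the offending neuron."""


@dataclass
class SimulationConfig:
    """Integration settings; defaults mirror the parameter file."""

    dt: float = 0.05  # ms
    duration_ms: float = 10_000.0
    transient_discard_ms: float = 1_000.0
    noise_sd: float = 1.5  # mV
    noise_tau: float = 1.0  # ms
    record_dt_ms: float = 1.0
    spike_threshold: float = 0.0  # mV
    spike_min_separation: float = 2.0  # ms
    seeds: dict = field(
        default_factory=lambda: {"connectome": 1, "drive": 2, "noise": 3}
    )
    record_ia: bool = False

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if not (self.duration_ms > self.transient_discard_ms >= 0):
            raise ConfigurationError("need duration > transient_discard >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    @classmethod
    def from_params(cls, params: dict, **overrides) -> "SimulationConfig":
        sim = params["simulation"]
        kwargs = dict(
            dt=sim["dt_ms"],
            duration_ms=sim["duration_ms"],
            transient_discard_ms=sim["transient_discard_ms"],
            noise_sd=sim["noise_sd_mv"],
            noise_tau=sim["noise_tau_ms"],
            record_dt_ms=sim["record_dt_ms"],
            spike_threshold=sim["spike_threshold_mv"],
            spike_min_separation=sim["spike_min_separation_ms"],
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class TrialRecording:
    """Everything one seeded trial produced.

    ``spikes[pop][i]`` is the (strictly increasing) spike-time array of
    neuron ``i`` in population ``pop``; ``lfp_source`` holds the summed
    synaptic current onto each pyramidal neuron, block-averaged onto the
    recording grid ``t_ms``; ``v_sum_pyr`` is the summed pyramidal somatic
    potential on the same grid.
    """

    t_ms: np.ndarray
    spikes: dict[str, list[np.ndarray]]
    lfp_source: np.ndarray  # (n_pyr, n_rec) µA/cm²
    v_sum_pyr: np.ndarray  # (n_rec,)
    v_example: dict[str, np.ndarray]
    dt: float
    seeds: dict
    config: dict
    ia_trace: np.ndarray | None = None

    @property
    def duration_ms(self) -> float:
        return self.config["duration_ms"]

    @property
    def transient_discard_ms(self) -> float:
        return self.config["transient_discard_ms"]

    def post_transient(self, x: np.ndarray) -> np.ndarray:
        """Restrict a recorded series to the analysis window."""
        keep = self.t_ms >= self.transient_discard_ms
        return x[..., keep]

    def spikes_post_transient(self, pop: str) -> list[np.ndarray]:
        t0 = self.transient_discard_ms
        return [s[s >= t0] for s in self.spikes[pop]]


# --- kernel input packing -------------------------------------------------


def _gate_tables(params: dict, gate_names: list[str], dt: float):
    v = np.arange(K.N_TAB) * K.V_TAB_STEP + K.V_TAB_MIN
    xinf = np.empty((len(gate_names), K.N_TAB))
    edt = np.empty((len(gate_names), K.N_TAB))
    for i, name in enumerate(gate_names):
        gk = build_gate_kinetics(params, name)
        xinf[i] = gk.steady_state(v)
        edt[i] = np.exp(-dt / gk.time_constant(v))
    return xinf, edt


def _roles(cell: dict, comp: str, channel: str):
    gates = cell[comp]["channels"][channel].get("gates", [])
    return [g["gate"] for g in gates], [g.get("exponent", 1) for g in gates]


def _pack_pyr(params: dict):
    cell = params["cells"]["pyramidal"]
    s = cell["soma"]["channels"]
    d = cell["dendrite"]["channels"]
    par = np.zeros(K.N_PP)
    par[K.PP_CM] = cell["cm"]
    par[K.PP_GC] = cell["g_c"]
    par[K.PP_P] = cell["p_soma"]
    par[K.PP_GNA], par[K.PP_ENA] = s["na"]["g_max"], s["na"]["e_rev"]
    par[K.PP_GK], par[K.PP_EK] = s["k"]["g_max"], s["k"]["e_rev"]
    par[K.PP_GLS], par[K.PP_ELS] = s["leak"]["g_max"], s["leak"]["e_rev"]
    par[K.PP_GCAS], par[K.PP_ECA] = s["ca"]["g_max"], s["ca"]["e_rev"]
    par[K.PP_GHS], par[K.PP_EH] = s["h"]["g_max"], s["h"]["e_rev"]
    par[K.PP_GAS], par[K.PP_EA] = s["a"]["g_max"], s["a"]["e_rev"]
    par[K.PP_GLD], par[K.PP_ELD] = d["leak"]["g_max"], d["leak"]["e_rev"]
    par[K.PP_GCAD] = d["ca"]["g_max"]
    par[K.PP_GHD] = d["h"]["g_max"]
    par[K.PP_GAD] = d.get("a", {"g_max": 0.0})["g_max"]
    par[K.PP_GAHP], par[K.PP_EAHP] = d["ahp"]["g_max"], d["ahp"]["e_rev"]
    par[K.PP_KDAHP] = d["ahp"].get("ca_kd", 1.0)
    par[K.PP_GCT], par[K.PP_ECT] = d["ct"]["g_max"], d["ct"]["e_rev"]
    par[K.PP_KDCT] = d["ct"].get("ca_kd", 1.0)
    pools = cell["pools"]
    par[K.PP_BAHP] = pools["ahp"]["b"]
    par[K.PP_TAUAHP] = pools["ahp"]["tau_ca"]
    par[K.PP_KAHP] = pools["ahp"].get("k_unit", 0.13)
    par[K.PP_BCT] = pools["ct"]["b"]
    par[K.PP_TAUCT] = pools["ct"]["tau_ca"]
    par[K.PP_KCT] = pools["ct"].get("k_unit", 0.13)
    par[K.PP_V0] = s["leak"]["e_rev"]
    na_g, na_e = _roles(cell, "soma", "na")
    k_g, k_e = _roles(cell, "soma", "k")
    ca_g, ca_e = _roles(cell, "soma", "ca")
    h_g, h_e = _roles(cell, "soma", "h")
    a_g, a_e = _roles(cell, "soma", "a")
    ct_g, ct_e = _roles(cell, "dendrite", "ct")
    gid_names = [na_g[0], na_g[1], k_g[0], ca_g[0], h_g[0], a_g[0], a_g[1], ct_g[0]]
    exps = [na_e[0], na_e[1], k_e[0], ca_e[0], h_e[0], a_e[0], a_e[1], ct_e[0]]
    return par, gid_names, np.asarray(exps, dtype=np.int64)


def _pack_simple(cell: dict, layout: str):
    s = cell["soma"]["channels"]
    if layout == "basket":
        par = np.zeros(K.N_BP)
        par[K.BP_CM] = cell["cm"]
        par[K.BP_GNA], par[K.BP_ENA] = s["na"]["g_max"], s["na"]["e_rev"]
        par[K.BP_GK], par[K.BP_EK] = s["k"]["g_max"], s["k"]["e_rev"]
        par[K.BP_GL], par[K.BP_EL] = s["leak"]["g_max"], s["leak"]["e_rev"]
        par[K.BP_V0] = s["leak"]["e_rev"]
        roles = ["na", "na", "k"]
    elif layout == "olm":
        par = np.zeros(K.N_OP)
        par[K.OP_CM] = cell["cm"]
        par[K.OP_GNA], par[K.OP_ENA] = s["na"]["g_max"], s["na"]["e_rev"]
        par[K.OP_GK], par[K.OP_EK] = s["k"]["g_max"], s["k"]["e_rev"]
        par[K.OP_GL], par[K.OP_EL] = s["leak"]["g_max"], s["leak"]["e_rev"]
        par[K.OP_GCA], par[K.OP_ECA] = s["ca"]["g_max"], s["ca"]["e_rev"]
        par[K.OP_GH], par[K.OP_EH] = s["h"]["g_max"], s["h"]["e_rev"]
        par[K.OP_GAHP], par[K.OP_EAHP] = s["ahp"]["g_max"], s["ahp"]["e_rev"]
        par[K.OP_KDAHP] = s["ahp"].get("ca_kd", 1.0)
        pool = cell["pools"]["ahp"]
        par[K.OP_BAHP] = pool["b"]
        par[K.OP_TAUAHP] = pool["tau_ca"]
        par[K.OP_KAHP] = pool.get("k_unit", 0.13)
        par[K.OP_V0] = s["leak"]["e_rev"]
        roles = ["na", "na", "k", "ca", "h"]
    else:  # msgaba
        par = np.zeros(K.N_MP)
        par[K.MP_CM] = cell["cm"]
        par[K.MP_GNA], par[K.MP_ENA] = s["na"]["g_max"], s["na"]["e_rev"]
        par[K.MP_GK], par[K.MP_EK] = s["k"]["g_max"], s["k"]["e_rev"]
        par[K.MP_GL], par[K.MP_EL] = s["leak"]["g_max"], s["leak"]["e_rev"]
        par[K.MP_GKS], par[K.MP_EKS] = s["ks"]["g_max"], s["ks"]["e_rev"]
        par[K.MP_V0] = s["leak"]["e_rev"]
        roles = ["na", "na", "k", "ks", "ks"]
    gid_names, exps = [], []
    cursors: dict[str, int] = {}
    for chan in roles:
        j = cursors.get(chan, 0)
        cursors[chan] = j + 1
        gates = s[chan].get("gates", [])
        gid_names.append(gates[j]["gate"])
        exps.append(gates[j].get("exponent", 1))
    return par, gid_names, np.asarray(exps, dtype=np.int64)


def _pack_projections(params: dict, connectome: Connectome, dt: float):
    projs = connectome.projections
    n_proj = len(projs)
    src = np.empty(n_proj, dtype=np.int64)
    tgt = np.empty(n_proj, dtype=np.int64)
    comp = np.empty(n_proj, dtype=np.int64)
    g = np.empty(n_proj)
    e = np.empty(n_proj)
    nmda = np.zeros(n_proj, dtype=np.int64)
    edd = np.empty(n_proj)
    edr = np.empty(n_proj)
    norm = np.empty(n_proj)
    ntgt = np.empty(n_proj, dtype=np.int64)
    indptr_parts, ptr_base = [], np.empty(n_proj, dtype=np.int64)
    tgt_parts, tgt_base = [], np.empty(n_proj, dtype=np.int64)
    state_base = np.empty(n_proj, dtype=np.int64)
    pops = populations_from_params(params)
    ptr_cursor = tgt_cursor = state_cursor = 0
    for i, (proj, pre) in enumerate(zip(projs, connectome.pre)):
        spec = proj.synapse
        src[i] = _POP_CODE[proj.source]
        tgt[i] = _POP_CODE[proj.target]
        comp[i] = 1 if proj.target_compartment == "dendrite" else 0
        g[i] = spec.g_max
        e[i] = spec.e_rev
        nmda[i] = 1 if spec.voltage_dependence else 0
        edd[i] = np.exp(-dt / spec.tau_decay)
        edr[i] = np.exp(-dt / spec.tau_rise)
        norm[i] = dual_exp_norm(spec.tau_rise, spec.tau_decay)
        n_tgt = pops[proj.target].n
        n_src = pops[proj.source].n
        ntgt[i] = n_tgt
        # invert per-target adjacency to out-lists per source (CSR)
        counts = np.zeros(n_src + 1, dtype=np.int64)
        for row in pre:
            for sidx in row:
                counts[sidx + 1] += 1
        indptr = np.cumsum(counts)
        targets = np.empty(indptr[-1], dtype=np.int64)
        fill = indptr[:-1].copy()
        for t, row in enumerate(pre):
            for sidx in row:
                targets[fill[sidx]] = t
                fill[sidx] += 1
        indptr_parts.append(indptr)
        tgt_parts.append(targets)
        ptr_base[i] = ptr_cursor
        tgt_base[i] = tgt_cursor
        state_base[i] = state_cursor
        ptr_cursor += len(indptr)
        tgt_cursor += len(targets)
        state_cursor += n_tgt
    csr_indptr = (
        np.concatenate(indptr_parts) if indptr_parts else np.zeros(0, dtype=np.int64)
    )
    csr_targets = (
        np.concatenate(tgt_parts) if tgt_parts else np.zeros(0, dtype=np.int64)
    )
    return (
        n_proj, src, tgt, comp, g, e, nmda, edd, edr, norm, ntgt,
        csr_indptr, ptr_base, csr_targets, tgt_base, state_base,
    )


def integrate_trial(
    params: dict,
    config: SimulationConfig,
    connectome: Connectome | None = None,
    drives: dict[str, np.ndarray] | None = None,
) -> TrialRecording:
    """Integrate one seeded trial and return its recording.

    If ``connectome``/``drives`` are omitted they are drawn from the seeds
    in ``config.seeds`` (keys ``connectome``, ``drive``, ``noise``), making
    the trial a pure function of parameters and seeds.
    """
    pops = populations_from_params(params)
    if connectome is None:
        projections = projections_from_params(params)
        sizes = {name: spec.n for name, spec in pops.items()}
        connectome = sample_connectome(
            projections, sizes, int(config.seeds["connectome"])
        )
    if drives is None:
        base = int(config.seeds["drive"])
        drives = {
            name: draw_heterogeneous_drive(pops[name], base + 13 * i)
            for i, name in enumerate(POP_ORDER)
        }

    dt = config.dt
    pyr_par, pyr_gnames, pyr_exp = _pack_pyr(params)
    bas_par, bas_gnames, bas_exp = _pack_simple(params["cells"]["basket"], "basket")
    olm_par, olm_gnames, olm_exp = _pack_simple(params["cells"]["olm"], "olm")
    msg_par, msg_gnames, msg_exp = _pack_simple(params["cells"]["msgaba"], "msgaba")
    gate_names: list[str] = []
    for name in pyr_gnames + bas_gnames + olm_gnames + msg_gnames:
        if name not in gate_names:
            gate_names.append(name)
    gidx = {n: i for i, n in enumerate(gate_names)}
    pyr_gid = np.asarray([gidx[n] for n in pyr_gnames], dtype=np.int64)
    bas_gid = np.asarray([gidx[n] for n in bas_gnames], dtype=np.int64)
    olm_gid = np.asarray([gidx[n] for n in olm_gnames], dtype=np.int64)
    msg_gid = np.asarray([gidx[n] for n in msg_gnames], dtype=np.int64)
    xinf_tab, edt_tab = _gate_tables(params, gate_names, dt)

    proj_pack = _pack_projections(params, connectome, dt)

    n_steps = int(round(config.duration_ms / dt))
    rec_stride = max(int(round(config.record_dt_ms / dt)), 1)
    noise_f = np.exp(-dt / config.noise_tau)
    noise_sig = (
        config.noise_sd * np.sqrt(1.0 - noise_f ** 2) if config.noise_sd > 0 else 0.0
    )
    n_total = sum(p.n for p in pops.values())
    max_spikes = int(n_total * config.duration_ms * 0.4) + 4096
    min_sep_steps = max(int(round(config.spike_min_separation / dt)), 1)

    n_comp = 2 * pops["pyramidal"].n + pops["basket"].n + pops["olm"].n + pops["msgaba"].n
    if noise_sig > 0:
        noise_rng = np.random.default_rng(int(config.seeds["noise"]) % (2 ** 31))
        noise_all = noise_rng.standard_normal(n_steps * n_comp, dtype=np.float32)
    else:
        noise_all = np.zeros(0, dtype=np.float32)
    out = K.run_network(
        dt, n_steps, rec_stride, noise_all,
        pops["pyramidal"].n, pops["basket"].n, pops["olm"].n, pops["msgaba"].n,
        pyr_par, bas_par, olm_par, msg_par,
        pyr_gid, pyr_exp, bas_gid, bas_exp, olm_gid, olm_exp, msg_gid, msg_exp,
        xinf_tab, edt_tab,
        np.asarray(drives["pyramidal"], dtype=float),
        np.asarray(drives["basket"], dtype=float),
        np.asarray(drives["olm"], dtype=float),
        np.asarray(drives["msgaba"], dtype=float),
        noise_f, noise_sig,
        *proj_pack,
        config.spike_threshold, min_sep_steps, max_spikes,
        1 if config.record_ia else 0,
    )
    (status, bad_neuron, spike_neuron, spike_step,
     lfp_pyr, vsum, v_example, ia_trace, rec_k) = out
    if status == K.STATUS_NAN:
        raise SimulationFault(
            f"non-finite membrane potential (global neuron index {bad_neuron})"
        )
    if status == K.STATUS_SPIKE_OVERFLOW:
        raise SimulationFault("spike buffer overflow: runaway firing")

    n_rec = n_steps // rec_stride
    t_ms = (np.arange(n_rec) + 1) * rec_stride * dt
    sizes = [pops[p].n for p in POP_ORDER]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    spikes: dict[str, list[np.ndarray]] = {}
    spike_t = spike_step.astype(float) * dt
    for pi, pop in enumerate(POP_ORDER):
        lists = []
        for i in range(sizes[pi]):
            gid = offsets[pi] + i
            lists.append(spike_t[spike_neuron == gid])
        spikes[pop] = lists
    v_ex = {
        "pyramidal_soma": v_example[0],
        "pyramidal_dendrite": v_example[1],
        "basket": v_example[2],
        "olm": v_example[3],
        "msgaba": v_example[4],
    }
    return TrialRecording(
        t_ms=t_ms,
        spikes=spikes,
        lfp_source=lfp_pyr,
        v_sum_pyr=vsum,
        v_example=v_ex,
        dt=dt,
        seeds=dict(config.seeds),
        config={
            "duration_ms": config.duration_ms,
            "transient_discard_ms": config.transient_discard_ms,
            "noise_sd": config.noise_sd,
            "noise_tau": config.noise_tau,
            "dt": dt,
            "record_dt_ms": config.record_dt_ms,
        },
        ia_trace=ia_trace if config.record_ia else None,
    )


def trial_seeds(base_seeds: dict, trial: int) -> dict:
    """Seed triple for one trial; trial 0 reuses the base seeds unchanged."""
    if trial == 0:
        return dict(base_seeds)
    out = {}
    for role_idx, role in enumerate(("connectome", "drive", "noise")):
        ss = np.random.SeedSequence([int(base_seeds[role]), role_idx, trial])
        out[role] = int(ss.generate_state(1)[0] % (2 ** 31))
    return out


def run_trials(
    params: dict, config: SimulationConfig, n_trials: int
) -> list[TrialRecording]:
    """Run ``n_trials`` independent patients: drives, connectome and noise
    are redrawn per trial from trial-indexed seeds."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    recordings = []
    for trial in range(n_trials):
        cfg = SimulationConfig(
            dt=config.dt,
            duration_ms=config.duration_ms,
            transient_discard_ms=config.transient_discard_ms,
            noise_sd=config.noise_sd,
            noise_tau=config.noise_tau,
            record_dt_ms=config.record_dt_ms,
            spike_threshold=config.spike_threshold,
            spike_min_separation=config.spike_min_separation,
            seeds=trial_seeds(config.seeds, trial),
            record_ia=config.record_ia,
        )
        try:
            recordings.append(integrate_trial(params, cfg))
        except SimulationFault as exc:
            raise SimulationFault(f"trial {trial}: {exc}") from exc
    return recordings


def detect_spikes(
    v: np.ndarray,
    threshold: float = 0.0,
    min_separation: float = 2.0,
    dt: float = 0.05,
) -> np.ndarray:
    """Upward threshold crossings of a voltage trace, merged within
    ``min_separation`` ms.  Returns crossing times in ms."""
    v = np.asarray(v, dtype=float)
    crossings = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1
    if crossings.size == 0:
        return np.zeros(0)
    times = crossings * dt
    keep = [times[0]]
    for t in times[1:]:
        if t - keep[-1] >= min_separation:
            keep.append(t)
    return np.asarray(keep)


# --- persistence ----------------------------------------------------------


def save_recording(rec: TrialRecording, path) -> None:
    """Persist a recording to an HDF5 container."""
    import json

    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("t_ms", data=rec.t_ms)
        f.create_dataset("lfp_source", data=rec.lfp_source)
        f.create_dataset("v_sum_pyr", data=rec.v_sum_pyr)
        grp = f.create_group("spikes")
        for pop, trains in rec.spikes.items():
            pgrp = grp.create_group(pop)
            for i, train in enumerate(trains):
                pgrp.create_dataset(str(i), data=train)
        vex = f.create_group("v_example")
        for key, trace in rec.v_example.items():
            vex.create_dataset(key, data=trace)
        f.attrs["config"] = json.dumps(rec.config)
        f.attrs["seeds"] = json.dumps(rec.seeds)
        f.attrs["dt"] = rec.dt


def load_recording(path) -> TrialRecording:
    import json

    import h5py

    with h5py.File(path, "r") as f:
        spikes = {}
        for pop in f["spikes"]:
            trains = f["spikes"][pop]
            spikes[pop] = [trains[str(i)][()] for i in range(len(trains))]
        return TrialRecording(
            t_ms=f["t_ms"][()],
            spikes=spikes,
            lfp_source=f["lfp_source"][()],
            v_sum_pyr=f["v_sum_pyr"][()],
            v_example={k: f["v_example"][k][()] for k in f["v_example"]},
            dt=float(f.attrs["dt"]),
            seeds=json.loads(f.attrs["seeds"]),
            config=json.loads(f.attrs["config"]),
        )


def export_raster(rec: TrialRecording, path) -> None:
    """Plain-text spike raster: global neuron id and spike time (ms)."""
    with open(path, "w") as fh:
        fh.write("# neuron_id\ttime_ms\n")
        gid = 0
        for pop in POP_ORDER:
            for train in rec.spikes.get(pop, []):
                for t in train:
                    fh.write(f"{gid}\t{t:.3f}\n")
                gid += 1
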