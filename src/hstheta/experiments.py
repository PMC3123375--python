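"""The channel-perturbation study: conditions, group runs, ANOVA, tables.

Amyloid-beta action is modeled purely as multiplicative changes to specific
pyramidal-cell parameters: the L-type calcium conductance (potentiation),
the delayed-rectifier and A-type potassium conductances (block), and the
fraction B of calcium influx feeding the BK-channel pool (potentiation or
block).  Each condition group is 15 seeded 10-s trials ("patients");
group differences are tested with one-way ANOVA against a shared control.

Trial seeds are shared across conditions, so condition contrasts are
matched on noise, heterogeneity and connectome realizations (a paired
design; the single-trial autocorrelation/spectrum contrast requires it).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .channels import ConfigurationError
from .engine import SimulationConfig, TrialRecording, run_trials
from .signal_analysis import (
    THETA_BAND,
    compute_lfp,
    lowpass_0_40,
    power_spectrum,
    relative_band_power,
)
from .synchrony import population_coherence, population_firing_rate

__all__ = [
    "ExperimentCondition",
    "GroupSummary",
    "AnovaResult",
    "apply_condition",
    "trial_metrics",
    "run_condition_group",
    "one_way_anova",
    "run_full_study",
    "DEFAULT_LADDERS",
    "CONTROL",
]

#: default scale ladders per perturbed channel (1.0 = control)
DEFAULT_LADDERS = {
    "g_ca": [1.5, 2.0, 3.0],  # potentiation
    "g_a_dendrite": [0.8, 0.6, 0.4],  # block, dendrite only
    "g_k": [0.8, 0.6, 0.4],  # block
    "b_ct": [0.0, 2.0, 3.0, 4.0, 5.0],  # full block and potentiation
    "g_a_both": [0.8, 0.6, 0.4],  # block, soma + dendrite
}

METRICS = ("theta_pct", "kappa", "rate_hz")


@dataclass(frozen=True)
class ExperimentCondition:
    """A multiplicative perturbation of one pyramidal channel parameter."""

    label: str
    target: str = "none"  # 'g_ca' | 'g_a' | 'g_k' | 'b_ct' | 'none'
    scale: float = 1.0
    scope: str = "both"  # 'soma' | 'dendrite' | 'both'

    def __post_init__(self):
        if self.scale < 0:
            raise ConfigurationError("scale must be non-negative")
        if self.target not in ("none", "g_ca", "g_a", "g_k", "b_ct"):
            raise ConfigurationError(f"unknown target {self.target!r}")
        if self.scope not in ("soma", "dendrite", "both"):
            raise ConfigurationError(f"unknown scope {self.scope!r}")


CONTROL = ExperimentCondition(label="control")


@dataclass
class GroupSummary:
    condition: ExperimentCondition
    values: dict[str, np.ndarray]  # metric -> per-trial values
    n_trials: int
    mean: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for metric, vals in self.values.items():
            self.mean[metric] = float(np.mean(vals))
            self.se[metric] = (
                float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1
                else 0.0
            )


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    labels: tuple[str, ...]


def apply_condition(params: dict, condition: ExperimentCondition) -> dict:
    """Return a deep-copied parameter set with the condition applied.

    Scales act on pyramidal-cell entries only; every other parameter is
    untouched.  A pure function: the input mapping is never mutated.
    """
    out = copy.deepcopy(params)
    if condition.target == "none":
        return out
    cell = out["cells"]["pyramidal"]
    comps = {
        "soma": ["soma"],
        "dendrite": ["dendrite"],
        "both": ["soma", "dendrite"],
    }[condition.scope]
    if condition.target == "g_ca":
        for comp in comps:
            cell[comp]["channels"]["ca"]["g_max"] *= condition.scale
    elif condition.target == "g_a":
        for comp in comps:
            if "a" in cell[comp]["channels"]:
                cell[comp]["channels"]["a"]["g_max"] *= condition.scale
    elif condition.target == "g_k":
        # the delayed rectifier lives in the soma
        cell["soma"]["channels"]["k"]["g_max"] *= condition.scale
    elif condition.target == "b_ct":
        cell["pools"]["ct"]["b"] *= condition.scale
    return out


def trial_metrics(
    rec: TrialRecording, tau_ms: float = 10.0
) -> dict[str, float]:
    """Per-trial metrics: relative theta power (%), pyramidal population
    coherence, and mean pyramidal firing rate (Hz)."""
    lfp = lowpass_0_40(compute_lfp(rec))
    spec = power_spectrum(lfp)
    theta = relative_band_power(spec, THETA_BAND)
    t_eff = rec.duration_ms - rec.transient_discard_ms
    trains = rec.spikes_post_transient("pyramidal")
    kappa = population_coherence(
        trains, t_total=t_eff, tau=tau_ms, t_start=rec.transient_discard_ms
    ).population_kappa
    _, rate = population_firing_rate(trains, t_eff)
    return {"theta_pct": theta, "kappa": kappa, "rate_hz": rate}


def run_condition_group(
    params: dict,
    condition: ExperimentCondition,
    config: SimulationConfig,
    n_trials: int = 15,
    tau_ms: float = 10.0,
    recordings_out: list | None = None,
) -> GroupSummary:
    """Run one condition group and compute per-trial metrics.

    Seeds come from ``config``; passing the same config to several
    conditions yields trial-matched (paired) groups.
    """
    perturbed = apply_condition(params, condition)
    recs = run_trials(perturbed, config, n_trials)
    if recordings_out is not None:
        recordings_out.extend(recs)
    rows = [trial_metrics(r, tau_ms) for r in recs]
    values = {m: np.array([r[m] for r in rows]) for m in METRICS}
    return GroupSummary(condition=condition, values=values, n_trials=n_trials)


def one_way_anova(
    groups: list[GroupSummary], metric: str = "theta_pct"
) -> AnovaResult:
    """Classical one-way ANOVA on trial-level metric values.

    Degenerate input (zero within-group variance with distinct means)
    yields p = 0 with a warning; fully identical groups yield F = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    samples = [np.asarray(g.values[metric], dtype=float) for g in groups]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs n >= 2")
    k = len(samples)
    n_total = sum(len(s) for s in samples)
    df_b, df_w = k - 1, n_total - k
    grand = np.concatenate(samples).mean()
    ss_b = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_w = sum(((s - s.mean()) ** 2).sum() for s in samples)
    labels = tuple(g.condition.label for g in groups)
    if ss_w == 0.0:
        if ss_b == 0.0:
            return AnovaResult(0.0, df_b, df_w, 1.0, labels)
        warnings.warn("zero within-group variance: ANOVA degenerate, p = 0")
        return AnovaResult(np.inf, df_b, df_w, 0.0, labels)
    f = (ss_b / df_b) / (ss_w / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p, labels)


def _ladder_conditions(ladders: dict[str, list[float]]) -> list[ExperimentCondition]:
    conds = []
    for key, scales in ladders.items():
        for s in scales:
            if key == "g_ca":
                conds.append(ExperimentCondition(f"{s:g}g_Ca", "g_ca", s, "both"))
            elif key == "g_a_dendrite":
                conds.append(ExperimentCondition(f"{s:g}g_A(dend)", "g_a", s, "dendrite"))
            elif key == "g_k":
                conds.append(ExperimentCondition(f"{s:g}g_K", "g_k", s, "soma"))
            elif key == "b_ct":
                conds.append(ExperimentCondition(f"{s:g}B", "b_ct", s, "both"))
            elif key == "g_a_both":
                conds.append(ExperimentCondition(f"{s:g}g_A(both)", "g_a", s, "both"))
            else:
                raise ConfigurationError(f"unknown ladder {key!r}")
    return conds


def run_full_study(
    params: dict,
    config: SimulationConfig,
    ladders: dict[str, list[float]] | None = None,
    n_trials: int = 15,
    tau_ms: float = 10.0,
) -> dict:
    """Execute every condition ladder against a shared control group.

    Returns a report dict with a tidy per-condition table (mean, SE and
    ANOVA p vs control for each metric) and the raw per-trial values.
    """
    ladders = DEFAULT_LADDERS if ladders is None else ladders
    control = run_condition_group(params, CONTROL, config, n_trials, tau_ms)
    groups = {"control": control}
    rows = []

    def add_row(summary: GroupSummary, ladder: str):
        row = {"ladder": ladder, "condition": summary.condition.label,
               "scale": summary.condition.scale, "n_trials": summary.n_trials}
        for m in METRICS:
            row[f"{m}_mean"] = summary.mean[m]
            row[f"{m}_se"] = summary.se[m]
            if summary.condition.label != "control":
                res = one_way_anova([groups["control"], summary], m)
                row[f"{m}_F"] = res.f
                row[f"{m}_p"] = res.p
        rows.append(row)

    add_row(control, "control")
    for cond in _ladder_conditions(ladders):
        summary = run_condition_group(params, cond, config, n_trials, tau_ms)
        groups[cond.label] = summary
        add_row(summary, _ladder_of(cond))
    table = pd.DataFrame(rows)
    return {
        "table": table,
        "groups": groups,
        "n_trials": n_trials,
        "tau_ms": tau_ms,
    }


def _ladder_of(cond: ExperimentCondition) -> str:
    if cond.target == "g_a":
        return "g_a_dendrite" if cond.scope == "dendrite" else "g_a_both"
    return cond.target
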