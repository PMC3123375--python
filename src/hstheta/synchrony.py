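"""Spike-train synchrony: binary-binned pairwise coherence and firing rates.

The coherence coefficient between two spike trains divides the interval T
into bins of width tau, marks each bin 1 if the neuron fired in it, and
normalizes the shared-bin count by the geometric mean of the individual
counts:

    kappa(i, j) = sum_l X(l) Y(l) / sqrt(sum_l X(l) * sum_l Y(l))

The population value averages kappa over all unordered pairs.  A train with
no spikes contributes kappa = 0 to its pairs (a silent neuron is maximally
unsynchronized) — a documented convention, since the ratio is otherwise
undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BinnedTrain",
    "CoherenceResult",
    "bin_spike_train",
    "pairwise_coherence",
    "population_coherence",
    "population_firing_rate",
]


@dataclass(frozen=True)
class BinnedTrain:
    tau: float  # bin width, ms
    t_total: float  # interval length, ms
    x: np.ndarray  # binary {0,1} vector, length floor(T/tau)

    def __post_init__(self):
        assert self.x.ndim == 1
        assert np.isin(self.x, (0, 1)).all()


@dataclass
class CoherenceResult:
    kappa: np.ndarray  # pairwise matrix, diagonal = 1 but excluded from mean
    population_kappa: float
    tau: float
    t_total: float


def bin_spike_train(
    spikes: np.ndarray, t_total: float, tau: float, t_start: float = 0.0
) -> BinnedTrain:
    """Binarize spike times into bins [(l-1)tau, l*tau) over [t_start, t_start+T)."""
    if tau <= 0 or t_total < tau:
        raise ValueError("need tau > 0 and T >= tau")
    n_bins = int(t_total // tau)
    x = np.zeros(n_bins, dtype=np.int8)
    spikes = np.asarray(spikes, dtype=float) - t_start
    idx = np.floor(spikes[(spikes >= 0) & (spikes < n_bins * tau)] / tau).astype(int)
    x[idx] = 1
    return BinnedTrain(tau=tau, t_total=t_total, x=x)


def pairwise_coherence(a: BinnedTrain, b: BinnedTrain) -> float:
    """Normalized shared-bin count; 0 for any silent train (convention)."""
    if a.x.size != b.x.size:
        raise ValueError("binned trains must share length")
    na = int(a.x.sum())
    nb = int(b.x.sum())
    if na == 0 or nb == 0:
        return 0.0
    shared = int(np.dot(a.x.astype(np.int64), b.x.astype(np.int64)))
    return shared / np.sqrt(na * nb)


def population_coherence(
    trains: list[np.ndarray], t_total: float, tau: float, t_start: float = 0.0
) -> CoherenceResult:
    """Mean pairwise coherence over all unordered neuron pairs."""
    if len(trains) < 2:
        raise ValueError("need at least two trains")
    binned = np.stack(
        [bin_spike_train(s, t_total, tau, t_start).x for s in trains]
    ).astype(np.float64)
    counts = binned.sum(axis=1)
    shared = binned @ binned.T
    denom = np.sqrt(np.outer(counts, counts))
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = np.where(denom > 0, shared / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(kappa, 1.0)
    n = len(trains)
    iu = np.triu_indices(n, k=1)
    return CoherenceResult(
        kappa=kappa,
        population_kappa=float(kappa[iu].mean()),
        tau=tau,
        t_total=t_total,
    )


def population_firing_rate(
    trains: list[np.ndarray], t_effective_ms: float
) -> tuple[np.ndarray, float]:
    """Per-neuron rates (Hz) from raw spike counts, and their mean."""
    if t_effective_ms <= 0:
        raise ValueError("effective duration must be positive")
    rates = np.array([len(s) for s in trains]) / (t_effective_ms / 1000.0)
    return rates, float(rates.mean())
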