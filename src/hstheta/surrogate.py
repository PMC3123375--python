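"""Surrogate signals with known ground truth for the analysis pipeline.

Two generators emulate the statistical structure the downstream stages
assume, so spectral, synchrony and statistics code is testable without the
biophysics:

* phase-clustered spike trains — inhomogeneous Poisson processes whose
  intensity is von-Mises modulated at a theta frequency; the concentration
  parameter maps monotonically from asynchronous (0) to tightly clustered;
* band-limited time series with an exactly controlled relative theta power,
  built in the frequency domain from equal-amplitude components on a 0.5 Hz
  grid over (0, 40] Hz plus a theta tone of calibrated amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import i0

from .signal_analysis import LfpTrace, THETA_BAND, TOTAL_BAND

__all__ = ["SurrogateSpec", "gen_phase_clustered_spikes", "gen_banded_timeseries"]


@dataclass(frozen=True)
class SurrogateSpec:
    n_neurons: int = 10
    theta_freq: float = 6.0  # Hz
    concentration: float = 0.0  # von Mises kappa; 0 = homogeneous Poisson
    base_rate: float = 5.0  # Hz, time-averaged per neuron
    duration_ms: float = 10_000.0
    theta_power_fraction: float = 0.3  # target for time-series surrogates
    seed: int = 0

    def __post_init__(self):
        if self.base_rate <= 0 or self.duration_ms <= 0:
            raise ValueError("rates and durations must be positive")
        if not (0.0 <= self.theta_power_fraction <= 1.0):
            raise ValueError("theta_power_fraction must lie in [0, 1]")


def gen_phase_clustered_spikes(spec: SurrogateSpec) -> list[np.ndarray]:
    """Spike trains with von-Mises-modulated intensity (thinning algorithm).

    lambda(t) = r * exp(kappa cos(2 pi f t)) / I0(kappa), so the time
    average equals the base rate for every concentration.
    """
    rng = np.random.default_rng(spec.seed)
    t_max_s = spec.duration_ms / 1000.0
    kap = spec.concentration
    lam_max = spec.base_rate * np.exp(kap) / i0(kap)
    trains = []
    for _ in range(spec.n_neurons):
        n_cand = rng.poisson(lam_max * t_max_s)
        cand = np.sort(rng.uniform(0.0, t_max_s, size=n_cand))
        lam = (
            spec.base_rate
            * np.exp(kap * np.cos(2 * np.pi * spec.theta_freq * cand))
            / i0(kap)
        )
        keep = rng.uniform(0.0, lam_max, size=n_cand) < lam
        trains.append(cand[keep] * 1000.0)  # ms
    return trains


def gen_banded_timeseries(spec: SurrogateSpec, fs: float = 1000.0) -> LfpTrace:
    """Time series whose expected relative theta power equals the target.

    The broadband floor has equal-amplitude random-phase components on a
    0.5 Hz grid over (0, 40] Hz; with no tone its theta share is the
    bandwidth ratio (3/40).  For targets above that ratio a tone at the
    theta frequency carries the excess; targets below the floor share are
    not reachable by adding power and fall back to the floor alone.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_ms / 1000.0 * fs))
    t = np.arange(n) / fs
    df = 0.5
    freqs = np.arange(df, TOTAL_BAND[1] + df / 2, df)
    m_total = freqs.size
    in_theta = (freqs > THETA_BAND[0]) & (freqs <= THETA_BAND[1])
    m_theta = int(in_theta.sum())
    a_noise = 1.0
    frac = spec.theta_power_fraction
    if frac >= 1.0:
        a_noise = 0.0
        tone_amp = 1.0
    else:
        excess = m_total * frac - m_theta
        tone_amp = (
            a_noise * np.sqrt(excess / (1.0 - frac)) if excess > 0 else 0.0
        )
    phases = rng.uniform(0, 2 * np.pi, size=m_total)
    x = np.zeros(n)
    if a_noise > 0:
        x += a_noise * np.sum(
            np.cos(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]), axis=0
        )
    if tone_amp > 0:
        f_tone = np.round(spec.theta_freq / df) * df
        x += tone_amp * np.cos(2 * np.pi * f_tone * t + rng.uniform(0, 2 * np.pi))
    return LfpTrace(
        t_ms=t * 1000.0, values=x, fs=fs, filter_descriptor="surrogate-banded"
    )
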