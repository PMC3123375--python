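"""LFP construction and spectral analysis.

The local field potential proxy is the summed synaptic current onto the
pyramidal population (open-field assumption), low-pass filtered to 0-40 Hz.
Spectra are averages of magnitude-squared FFTs over 2-s Hann-tapered
segments (50% overlap), giving 0.5 Hz resolution; band powers are reported
as percent of the total (0, 40] Hz power with the DC bin excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .engine import TrialRecording

__all__ = [
    "LfpTrace",
    "SpectralResult",
    "compute_lfp",
    "lowpass_0_40",
    "power_spectrum",
    "relative_band_power",
    "autocorrelation",
    "THETA_BAND",
    "TOTAL_BAND",
]

THETA_BAND = (4.0, 7.0)  # Hz
TOTAL_BAND = (0.0, 40.0)  # Hz; DC excluded in band-power ratios


@dataclass
class LfpTrace:
    t_ms: np.ndarray
    values: np.ndarray
    fs: float  # Hz
    filter_descriptor: str = "raw"

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("LFP trace contains non-finite values")


@dataclass
class SpectralResult:
    freqs: np.ndarray  # Hz
    power: np.ndarray
    window_s: float
    overlap: float
    n_segments: int


def compute_lfp(recording: TrialRecording, discard_transient: bool = True) -> LfpTrace:
    """Sum the recorded synaptic currents over all pyramidal neurons."""
    if recording.lfp_source.size == 0:
        raise ValueError("recording has no pyramidal synaptic-current channel")
    values = recording.lfp_source.sum(axis=0)
    t = recording.t_ms
    if discard_transient:
        keep = t >= recording.transient_discard_ms
        t, values = t[keep], values[keep]
    fs = 1000.0 / (t[1] - t[0])
    return LfpTrace(t_ms=t, values=values, fs=fs)


def lowpass_0_40(x: LfpTrace, cutoff_hz: float = 40.0, order: int = 4) -> LfpTrace:
    """Zero-phase low-pass (forward-backward 4th-order Butterworth)."""
    if x.fs <= 2 * cutoff_hz:
        raise ValueError("sampling rate too low for the requested cutoff")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=x.fs, output="sos")
    padlen = min(3 * (2 * order + 1), x.values.size - 1)
    if x.values.size < 3 * padlen:
        raise ValueError("trace shorter than the filter warm-up")
    filtered = sps.sosfiltfilt(sos, x.values, padlen=padlen)
    return LfpTrace(
        t_ms=x.t_ms, values=filtered, fs=x.fs,
        filter_descriptor=f"butter{order}-lowpass-{cutoff_hz}Hz-zerophase",
    )


def power_spectrum(
    x: LfpTrace, window_s: float = 2.0, overlap: float = 0.5
) -> SpectralResult:
    """Welch average of Hann-tapered segment spectra."""
    nperseg = int(round(window_s * x.fs))
    if x.values.size < nperseg:
        raise ValueError(
            f"trace of {x.values.size} samples shorter than one "
            f"{window_s:g}-s window"
        )
    noverlap = int(round(nperseg * overlap))
    freqs, power = sps.welch(
        x.values - x.values.mean(),
        fs=x.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
    )
    n_segments = 1 + (x.values.size - nperseg) // (nperseg - noverlap)
    return SpectralResult(
        freqs=freqs, power=power, window_s=window_s, overlap=overlap,
        n_segments=n_segments,
    )


def relative_band_power(
    spec: SpectralResult,
    band: tuple[float, float] = THETA_BAND,
    total_band: tuple[float, float] = TOTAL_BAND,
) -> float:
    """Band power as percent of total power over ``total_band``; DC excluded.

    Band edges are inclusive, so a partition like {0-4, 4-7, 7-40} Hz
    double-counts nothing only if callers use half-open conventions; here
    the lower edge is exclusive and the upper inclusive, which makes such a
    partition sum to exactly 100%.
    """
    f_lo, f_hi = band
    if not (total_band[0] <= f_lo < f_hi <= total_band[1]):
        raise ValueError("band must be a non-empty sub-interval of the total band")
    f = spec.freqs
    in_total = (f > total_band[0]) & (f <= total_band[1])
    in_band = (f > f_lo) & (f <= f_hi)
    total = spec.power[in_total].sum()
    if total == 0:
        return 0.0
    return 100.0 * spec.power[in_band & in_total].sum() / total


def autocorrelation(x: np.ndarray, max_lag_ms: float, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Normalized autocorrelation (1 at zero lag) up to ``max_lag_ms``.

    Input is typically the summed pyramidal membrane potential; returns
    (lags_ms, acf).
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    max_lag = min(int(round(max_lag_ms * fs / 1000.0)), n - 1)
    denom = float(np.dot(x, x))
    if denom == 0.0:
        acf = np.zeros(max_lag + 1)
        acf[0] = 1.0
    else:
        full = sps.correlate(x, x, mode="full", method="fft")
        acf = full[n - 1 : n + max_lag] / denom
    lags = np.arange(max_lag + 1) / fs * 1000.0
    return lags, acf
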