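"""Multitaper PSD and coherence with RMS normalization and banded peaks.

Spectra are estimated on 2 s sliding windows with 1 s overlap using 3
orthogonal DPSS (Slepian) tapers at time-bandwidth NW = 2 (the standard
minimal-leakage choice admitting exactly 3 tapers). Per-window, per-taper
periodograms are averaged over tapers then windows; PSD carries density
scaling (units^2/Hz) before normalization. Epoch PSDs are normalized by the
epoch's signal RMS; theta-band summaries take the peak value in 5-12 Hz.

Magnitude-squared coherence averages the cross- and auto-spectra over all
window-taper estimates: ``|<Sxy>|^2 / (<Sxx><Syy>)``. RMS normalization
cancels in this ratio and is not applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss

__all__ = [
    "SpectralParams",
    "PSDResult",
    "CoherenceResult",
    "BandPeak",
    "SpectralError",
    "spectral_windows",
    "multitaper_psd",
    "rms_normalize",
    "multitaper_coherence",
    "peak_in_band",
]

THETA_BAND = (5.0, 12.0)


class SpectralError(ValueError):
    """Raised when a spectral estimate is undefined (e.g. no clean windows)."""


@dataclass(frozen=True)
class SpectralParams:
    window_s: float = 2.0
    overlap_s: float = 1.0
    n_tapers: int = 3
    time_bandwidth: float = 2.0

    def __post_init__(self):
        if not 0 <= self.overlap_s < self.window_s:
            raise ValueError("need 0 <= overlap_s < window_s")
        if self.n_tapers > 2 * self.time_bandwidth - 1:
            raise ValueError("n_tapers must be <= 2*time_bandwidth - 1")

    def n_per_window(self, fs: float) -> int:
        return int(round(self.window_s * fs))

    def step(self, fs: float) -> int:
        return self.n_per_window(fs) - int(round(self.overlap_s * fs))


@dataclass
class PSDResult:
    freqs: np.ndarray
    power: np.ndarray
    n_windows: int
    normalization: str = "raw"  # "raw" | "rms"


@dataclass
class CoherenceResult:
    freqs: np.ndarray
    coherence: np.ndarray
    n_windows: int


@dataclass(frozen=True)
class BandPeak:
    freq: float
    value: float
    band: tuple[float, float]


def spectral_windows(
    n_samples: int, fs: float, params: SpectralParams = SpectralParams()
) -> list[tuple[int, int]]:
    """Sliding analysis windows as half-open sample intervals."""
    win = params.n_per_window(fs)
    step = params.step(fs)
    return [(s, s + win) for s in range(0, n_samples - win + 1, step)]


def _tapers(win: int, params: SpectralParams) -> np.ndarray:
    w = dpss(win, NW=params.time_bandwidth, Kmax=params.n_tapers)
    return w / np.sqrt(np.sum(w**2, axis=1, keepdims=True))  # unit energy


def _check_windows(
    x_len: int, fs: float, params: SpectralParams, windows
) -> list[tuple[int, int]]:
    if windows is None:
        windows = spectral_windows(x_len, fs, params)
    windows = list(windows)
    if not windows:
        raise SpectralError("no clean analysis windows available")
    win = params.n_per_window(fs)
    for s, e in windows:
        if e - s != win:
            raise SpectralError(f"window ({s}, {e}) is not {params.window_s} s long")
        if not (0 <= s < e <= x_len):
            raise SpectralError(f"window ({s}, {e}) outside signal bounds")
    return windows


def _taper_spectra(seg: np.ndarray, tapers: np.ndarray) -> np.ndarray:
    """Complex spectra per taper: shape (K, n_freqs)."""
    return rfft(seg[None, :] * tapers, axis=1)


def _one_sided(power: np.ndarray, win: int) -> np.ndarray:
    power = power.copy()
    power[..., 1:] *= 2.0
    if win % 2 == 0:
        power[..., -1] /= 2.0
    return power


def multitaper_psd(
    x: np.ndarray,
    fs: float,
    params: SpectralParams = SpectralParams(),
    windows: list[tuple[int, int]] | None = None,
) -> PSDResult:
    """Multitaper power spectral density, averaged over tapers then windows."""
    x = np.asarray(x, dtype=float)
    windows = _check_windows(len(x), fs, params, windows)
    win = params.n_per_window(fs)
    tapers = _tapers(win, params)
    freqs = rfftfreq(win, 1.0 / fs)
    acc = np.zeros(freqs.size)
    for s, e in windows:
        spec = _taper_spectra(x[s:e], tapers)
        acc += _one_sided(np.abs(spec) ** 2 / fs, win).mean(axis=0)
    return PSDResult(freqs=freqs, power=acc / len(windows), n_windows=len(windows))


def rms_normalize(psd: PSDResult, signal: np.ndarray) -> PSDResult:
    """Divide the PSD by the RMS of the epoch's (clean) samples."""
    if psd.normalization == "rms":
        raise ValueError("PSD is already RMS-normalized")
    rms = float(np.sqrt(np.mean(np.asarray(signal, dtype=float) ** 2)))
    if rms <= 0:
        raise ValueError("signal RMS is zero; normalization undefined")
    return replace(psd, power=psd.power / rms, normalization="rms")


def multitaper_coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    params: SpectralParams = SpectralParams(),
    windows: list[tuple[int, int]] | None = None,
) -> CoherenceResult:
    """Magnitude-squared coherence from pooled window-taper estimates."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("channels must have equal length")
    windows = _check_windows(len(x), fs, params, windows)
    if len(windows) * params.n_tapers < 2:
        raise SpectralError("coherence needs at least 2 window-taper estimates")
    win = params.n_per_window(fs)
    tapers = _tapers(win, params)
    freqs = rfftfreq(win, 1.0 / fs)
    sxx = np.zeros(freqs.size)
    syy = np.zeros(freqs.size)
    sxy = np.zeros(freqs.size, dtype=complex)
    for s, e in windows:
        fx = _taper_spectra(x[s:e], tapers)
        fy = _taper_spectra(y[s:e], tapers)
        sxx += (np.abs(fx) ** 2).sum(axis=0)
        syy += (np.abs(fy) ** 2).sum(axis=0)
        sxy += (fx * np.conj(fy)).sum(axis=0)
    denom = sxx * syy
    coh = np.zeros(freqs.size)
    ok = denom > 0
    coh[ok] = np.abs(sxy[ok]) ** 2 / denom[ok]
    return CoherenceResult(freqs=freqs, coherence=np.clip(coh, 0.0, 1.0), n_windows=len(windows))


def peak_in_band(
    result: PSDResult | CoherenceResult,
    band: tuple[float, float] = THETA_BAND,
) -> BandPeak:
    """Maximum value and its frequency within the closed band; ties -> lowest f."""
    lo, hi = band
    values = result.power if isinstance(result, PSDResult) else result.coherence
    sel = (result.freqs >= lo) & (result.freqs <= hi)
    if not np.any(sel):
        raise ValueError(f"band [{lo}, {hi}] Hz does not intersect the frequency grid")
    f_band = result.freqs[sel]
    v_band = values[sel]
    i = int(np.argmax(v_band))  # argmax returns the first (lowest-f) maximum
    return BandPeak(freq=float(f_band[i]), value=float(v_band[i]), band=(lo, hi))
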