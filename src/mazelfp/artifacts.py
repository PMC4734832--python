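"""Automated burst-artifact scrubbing.

Shake artifacts show up as high-amplitude burst oscillations. Detection
scans the signal with 0.25 s windows (50% overlap) and flags a window when
its RMS, or its broadband (>15 Hz) power, exceeds a robust threshold
(median + k * 1.4826 * MAD over the epoch's window statistics). Flagged
windows merge into intervals whose edges are then tightened to the
supra-threshold extent of a short-scale moving-RMS envelope, so a flagged
interval tracks the burst rather than the window grid. Thresholds are
relative, so detection is invariant to global amplitude scaling.

The scrub report summarizes the recovered-signal fraction
(clean / total duration) per channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "ArtifactMask",
    "ScrubReport",
    "detect_artifacts",
    "recovered_fraction",
    "mask_windows",
]

SampleInterval = tuple[int, int]


@dataclass
class ArtifactMask:
    """Per-channel flagged sample intervals (half-open, sorted, merged)."""

    intervals: dict[str, list[SampleInterval]]
    n_samples: int
    fs: float

    def __post_init__(self):
        for ch, ivs in self.intervals.items():
            self.intervals[ch] = _merge(ivs)
            for a, b in self.intervals[ch]:
                if not (0 <= a < b <= self.n_samples):
                    raise ValueError(f"interval ({a}, {b}) outside signal bounds on {ch}")

    def flagged_samples(self, channel: str) -> int:
        return sum(b - a for a, b in self.intervals[channel])

    def intervals_seconds(self, channel: str) -> list[tuple[float, float]]:
        return [(a / self.fs, b / self.fs) for a, b in self.intervals[channel]]

    def boolean(self, channel: str) -> np.ndarray:
        """True where flagged."""
        m = np.zeros(self.n_samples, dtype=bool)
        for a, b in self.intervals[channel]:
            m[a:b] = True
        return m


@dataclass
class ScrubReport:
    """Recovered-signal summary per channel; fraction = clean / total."""

    clean_seconds: dict[str, float]
    total_seconds: float
    recovered: dict[str, float]

    @property
    def mean_recovered(self) -> float:
        return float(np.mean(list(self.recovered.values())))


def _merge(intervals) -> list[SampleInterval]:
    out: list[list[int]] = []
    for a, b in sorted(intervals):
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([int(a), int(b)])
    return [(a, b) for a, b in out]


def _window_stat(cum2: np.ndarray, starts: np.ndarray, win: int) -> np.ndarray:
    return np.sqrt((cum2[starts + win] - cum2[starts]) / win)


def _robust_flags(stat: np.ndarray, k_mad: float) -> np.ndarray:
    med = np.median(stat)
    mad = np.median(np.abs(stat - med))
    if mad <= 1e-12 * max(abs(med), 1e-30):
        # Degenerate spread (constant or zero signal): nothing to flag.
        return np.zeros(stat.shape, dtype=bool)
    return stat > med + k_mad * 1.4826 * mad


def _moving_rms(x: np.ndarray, win: int) -> np.ndarray:
    cum = np.concatenate([[0.0], np.cumsum(x**2)])
    n = len(x)
    half = win // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    return np.sqrt((cum[hi] - cum[lo]) / (hi - lo))


def _detect_channel(
    x: np.ndarray,
    fs: float,
    window_s: float,
    k_mad: float,
    step_s: float | None,
    refine: bool,
) -> list[SampleInterval]:
    n = len(x)
    win = int(round(window_s * fs))
    if n < win:
        raise ValueError(f"signal shorter than one {window_s} s window")
    step = max(1, int(round((step_s if step_s is not None else window_s / 2.0) * fs)))
    starts = np.arange(0, n - win + 1, step)
    if starts[-1] != n - win:
        starts = np.append(starts, n - win)

    cum2 = np.concatenate([[0.0], np.cumsum(x**2)])
    rms = _window_stat(cum2, starts, win)
    flags = _robust_flags(rms, k_mad)

    if fs > 40.0:  # broadband check needs room above 15 Hz
        sos = butter(4, 15.0, btype="highpass", fs=fs, output="sos")
        hp = sosfiltfilt(sos, x)
        cum2_hp = np.concatenate([[0.0], np.cumsum(hp**2)])
        flags |= _robust_flags(_window_stat(cum2_hp, starts, win), k_mad)

    coarse = _merge([(int(s), int(s + win)) for s, f in zip(starts, flags) if f])
    if not refine or not coarse:
        return coarse

    # Tighten interval edges to the burst itself: short-scale moving RMS
    # against the same robust threshold, padded by 50 ms.
    env = _moving_rms(x, max(2, int(round(0.1 * fs))))
    med = np.median(env)
    mad = np.median(np.abs(env - med))
    if mad <= 1e-12 * max(abs(med), 1e-30):
        return coarse
    thr = med + k_mad * 1.4826 * mad
    pad = int(round(0.05 * fs))
    refined: list[SampleInterval] = []
    for a, b in coarse:
        above = np.flatnonzero(env[a:b] > thr)
        if above.size == 0:
            refined.append((a, b))
        else:
            refined.append(
                (max(0, a + int(above[0]) - pad), min(n, a + int(above[-1]) + 1 + pad))
            )
    return _merge(refined)


def detect_artifacts(
    signal: np.ndarray,
    fs: float,
    window_s: float = 0.25,
    k_mad: float = 6.0,
    step_s: float | None = None,
    refine: bool = True,
    channel_labels: tuple[str, ...] | None = None,
) -> ArtifactMask:
    """Flag burst artifacts in a 1-D signal or (n_channels, n_samples) array."""
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    if channel_labels is None:
        channel_labels = tuple(f"ch{i}" for i in range(x.shape[0]))
    if len(channel_labels) != x.shape[0]:
        raise ValueError("one label per channel required")
    intervals = {
        lb: _detect_channel(x[i], fs, window_s, k_mad, step_s, refine)
        for i, lb in enumerate(channel_labels)
    }
    return ArtifactMask(intervals, n_samples=x.shape[1], fs=fs)


def recovered_fraction(mask: ArtifactMask) -> ScrubReport:
    """Fraction of the signal surviving artifact removal, per channel."""
    total = mask.n_samples / mask.fs
    clean = {
        ch: (mask.n_samples - mask.flagged_samples(ch)) / mask.fs
        for ch in mask.intervals
    }
    recovered = {ch: c / total for ch, c in clean.items()}
    return ScrubReport(clean_seconds=clean, total_seconds=total, recovered=recovered)


def mask_windows(
    mask: ArtifactMask,
    windows: list[SampleInterval],
    channel: str,
) -> list[SampleInterval]:
    """Drop any analysis window overlapping a flagged interval (no splicing)."""
    flagged = mask.intervals[channel]
    kept = []
    for s, e in windows:
        if not (0 <= s < e <= mask.n_samples):
            raise ValueError(f"window ({s}, {e}) outside signal bounds")
        if not any(a < e and s < b for a, b in flagged):
            kept.append((s, e))
    if flagged and not kept and windows:
        warnings.warn("all analysis windows overlap artifacts", stacklevel=2)
    return kept
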