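"""Ground-truth synthetic LFP sessions.

The generator emulates the statistical structure the analysis assumes, with
known parameters so every downstream estimate can be checked against the
truth that produced it:

* a theta rhythm (5-12 Hz band) whose phase multiplicatively modulates the
  amplitude of a gamma-band oscillation (Tort-style ``(1 + cos)/2`` envelope),
* a 1/f^alpha broadband noise floor,
* controllable between-channel theta coherence via a shared/independent
  narrowband-theta mixture,
* high-amplitude "shake" burst artifacts at Poisson onsets with recorded
  ground-truth intervals,

organized into pre-maze baseline, per-trial maze swim and on-platform
consolidation segments. Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import hilbert
from scipy.signal.windows import tukey

from .filters import bandpass_zero_phase
from .io import EventTable, Recording

__all__ = [
    "CouplingSpec",
    "ArtifactSpec",
    "SessionSpec",
    "GroundTruth",
    "pink_noise",
    "generate_coupled_signal",
    "generate_coupled_process",
    "inject_artifacts",
    "generate_session",
    "default_phase_coupling",
]


@dataclass(frozen=True)
class CouplingSpec:
    """Parameters of one phase-amplitude-coupled signal.

    ``coupling_strength`` (c) is the fraction of the gamma amplitude riding
    on theta phase: the gamma envelope is
    ``gamma_amp * ((1 - c) + c * (1 + cos(theta_phase + phi0)) / 2)``,
    so c = 0 gives a constant envelope and c = 1 a fully modulated one that
    vanishes at the phase where the cosine is -1.
    """

    f_theta: float = 8.0
    f_gamma: float = 60.0
    coupling_strength: float = 0.5
    theta_amp: float = 1.0
    gamma_amp: float = 0.5
    noise_exponent: float = 1.5
    noise_amp: float = 0.5
    phi0: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must be in [0, 1]")
        if not 0.0 < self.f_theta < self.f_gamma:
            raise ValueError("need 0 < f_theta < f_gamma")
        if min(self.theta_amp, self.gamma_amp, self.noise_amp) < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass(frozen=True)
class ArtifactSpec:
    """Shake-burst artifact statistics.

    Bursts occur at Poisson onsets (``rate`` events/s), last
    Gamma-distributed times with mean ``duration_mean`` s, and oscillate at
    ``burst_freq`` Hz with peak amplitude ``burst_amp_factor`` times the
    clean-signal RMS.
    """

    rate: float = 0.02
    duration_mean: float = 1.0
    burst_freq: float = 15.0
    burst_amp_factor: float = 8.0

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.duration_mean <= 0:
            raise ValueError("duration_mean must be positive")
        if self.burst_amp_factor <= 1:
            raise ValueError("burst_amp_factor must exceed 1")


def default_phase_coupling() -> dict[str, CouplingSpec]:
    """Per-task-phase coupling defaults.

    Maze swimming carries twice the baseline theta amplitude and the
    strongest theta-gamma coupling; the platform sits in between. These are
    the study conditions every qualitative-recovery check runs under.
    """
    base = CouplingSpec()
    return {
        "pre_maze": replace(base, theta_amp=1.0, coupling_strength=0.4),
        "maze": replace(base, theta_amp=2.0, coupling_strength=0.8),
        "platform": replace(base, theta_amp=1.2, coupling_strength=0.6),
    }


def _default_coherence() -> dict[str, float]:
    return {"pre_maze": 0.5, "maze": 0.8, "platform": 0.7}


@dataclass(frozen=True)
class SessionSpec:
    """Layout and generative parameters of a full two-channel session."""

    fs: float = 1000.0
    pre_maze_duration: float = 60.0
    n_trials: int = 4
    trial_durations: float | tuple[float, ...] = 12.0
    platform_duration: float = 15.0
    coupling: dict[str, CouplingSpec] | None = None
    theta_coherence: float | dict[str, float] | None = None
    theta_bandwidth: float = 2.0
    artifact_spec: ArtifactSpec | None = None
    channel_labels: tuple[str, str] = ("dCA1", "dlSTR")
    seed: int = 0

    def resolved_trial_durations(self) -> tuple[float, ...]:
        d = self.trial_durations
        if np.isscalar(d):
            return tuple([float(d)] * self.n_trials)
        d = tuple(float(v) for v in d)
        if len(d) != self.n_trials:
            raise ValueError(f"{len(d)} trial durations for {self.n_trials} trials")
        return d

    def resolved_coupling(self) -> dict[str, CouplingSpec]:
        return dict(self.coupling) if self.coupling is not None else default_phase_coupling()

    def resolved_coherence(self) -> dict[str, float]:
        c = self.theta_coherence
        if c is None:
            return _default_coherence()
        if np.isscalar(c):
            c = {ph: float(c) for ph in ("pre_maze", "maze", "platform")}
        for v in c.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("theta_coherence must be in [0, 1]")
        return dict(c)

    def __post_init__(self):
        if min(self.pre_maze_duration, self.platform_duration) <= 0:
            raise ValueError("durations must be positive")
        if any(d <= 0 for d in self.resolved_trial_durations()):
            raise ValueError("durations must be positive")
        self.resolved_coherence()


@dataclass
class GroundTruth:
    """What the generator actually did, for validating detectors/estimators."""

    artifact_intervals: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    phase_coupling: dict[str, CouplingSpec] | None = None
    theta_coherence: dict[str, float] | None = None


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

def _pink_scales(n: int, fs: float, exponent: float) -> np.ndarray:
    f = np.fft.rfftfreq(n, 1.0 / fs)
    s = np.zeros_like(f)
    s[1:] = f[1:] ** (-exponent / 2.0)
    return s


def pink_noise(n: int, fs: float, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise by spectral shaping of white noise."""
    s = _pink_scales(n, fs, exponent)
    spec = (rng.standard_normal(s.size) + 1j * rng.standard_normal(s.size)) * s
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = spec[-1].real
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def pink_band_fraction(n: int, fs: float, exponent: float, f_lo: float, f_hi: float) -> float:
    """Fraction of 1/f^exponent noise variance falling in [f_lo, f_hi] Hz."""
    f = np.fft.rfftfreq(n, 1.0 / fs)
    p = _pink_scales(n, fs, exponent) ** 2
    total = p.sum()
    if total == 0:
        return 0.0
    return float(p[(f >= f_lo) & (f <= f_hi)].sum() / total)


def generate_coupled_signal(
    spec: CouplingSpec,
    duration: float,
    fs: float,
    seed: int,
    label: str = "ch0",
) -> Recording:
    """Single-channel phase-amplitude-coupled signal.

    ``x(t) = theta_amp sin(2 pi f_theta t)
           + gamma_amp [(1 - c) + c (1 + cos(2 pi f_theta t + phi0)) / 2]
             sin(2 pi f_gamma t)
           + noise_amp * pink(t)``
    """
    if spec.f_gamma >= fs / 2.0:
        raise ValueError(f"f_gamma={spec.f_gamma} Hz would alias at fs={fs} Hz")
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    c = spec.coupling_strength
    theta = spec.theta_amp * np.sin(2 * np.pi * spec.f_theta * t)
    env = spec.gamma_amp * (
        (1.0 - c) + c * (1.0 + np.cos(2 * np.pi * spec.f_theta * t + spec.phi0)) / 2.0
    )
    x = theta + env * np.sin(2 * np.pi * spec.f_gamma * t)
    if spec.noise_amp > 0:
        x = x + spec.noise_amp * pink_noise(n, fs, spec.noise_exponent, rng)
    return Recording(x[None, :], fs, (label,))


def _narrowband_theta(
    coupling: CouplingSpec,
    theta_bandwidth: float,
    n: int,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-RMS stochastic theta: bandpassed white noise around f_theta."""
    f_lo = coupling.f_theta - theta_bandwidth / 2.0
    f_hi = coupling.f_theta + theta_bandwidth / 2.0
    x = bandpass_zero_phase(rng.standard_normal(n), fs, f_lo, f_hi)
    r = np.sqrt(np.mean(x**2))
    return x / r if r > 0 else x


def _stochastic_channel(
    coupling: CouplingSpec,
    theta: np.ndarray,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gamma modulated by the instantaneous phase of a given theta trace."""
    n = theta.size
    t = np.arange(n) / fs
    c = coupling.coupling_strength
    phase = np.angle(hilbert(theta))
    env = coupling.gamma_amp * (
        (1.0 - c) + c * (1.0 + np.cos(phase + coupling.phi0)) / 2.0
    )
    gamma = env * np.sin(2 * np.pi * coupling.f_gamma * t + rng.uniform(0, 2 * np.pi))
    noise = coupling.noise_amp * pink_noise(n, fs, coupling.noise_exponent, rng)
    return theta + gamma + noise


def generate_coupled_process(
    spec: CouplingSpec,
    duration: float,
    fs: float,
    seed: int,
    theta_bandwidth: float = 2.0,
    label: str = "ch0",
) -> Recording:
    """Coupled signal with a *stochastic* narrowband theta.

    Unlike :func:`generate_coupled_signal`, theta here is a band-limited
    noise process whose phase drifts, as in-vivo theta does. This is the
    variant to use when testing time-shift surrogate statistics: a strictly
    periodic signal keeps its phase-amplitude coupling under any circular
    shift (the shift only rotates the preferred phase), so shift surrogates
    can only null out coupling when theta decorrelates over the shift.
    """
    if spec.f_gamma >= fs / 2.0:
        raise ValueError(f"f_gamma={spec.f_gamma} Hz would alias at fs={fs} Hz")
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    theta = (spec.theta_amp / np.sqrt(2.0)) * _narrowband_theta(
        spec, theta_bandwidth, n, fs, rng
    )
    return Recording(_stochastic_channel(spec, theta, fs, rng)[None, :], fs, (label,))


def _merge_time_intervals(
    intervals: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    merged: list[list[float]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def inject_artifacts(
    recording: Recording,
    spec: ArtifactSpec,
    seed: int,
) -> tuple[Recording, GroundTruth]:
    """Add shake bursts to every channel; return the true artifact intervals.

    A shake hits the whole headstage, so burst events are shared across
    channels (scaled per channel to ``burst_amp_factor`` times that channel's
    clean RMS); the ground truth records identical intervals per channel.
    Burst durations are Gamma(shape 4) with mean ``duration_mean`` and a
    floor of two burst cycles; the waveform is a Tukey-tapered sinusoid.
    """
    if recording.n_samples == 0:
        raise ValueError("empty recording")
    out = recording.copy()
    if spec.rate == 0:
        gt = GroundTruth(artifact_intervals={lb: [] for lb in recording.channel_labels})
        return out, gt
    rng = np.random.default_rng(seed)
    fs, n = recording.fs, recording.n_samples
    total_t = n / fs
    n_events = rng.poisson(spec.rate * total_t)
    onsets = np.sort(rng.uniform(0.0, total_t, n_events))
    durations = rng.gamma(4.0, spec.duration_mean / 4.0, n_events)
    durations = np.maximum(durations, 2.0 / spec.burst_freq)
    phases = rng.uniform(0.0, 2 * np.pi, n_events)

    rms = np.sqrt(np.mean(recording.samples**2, axis=1))
    intervals: list[tuple[float, float]] = []
    for onset, dur, ph in zip(onsets, durations, phases):
        i0 = int(np.floor(onset * fs))
        i1 = min(n, int(np.floor((onset + dur) * fs)))
        if i1 - i0 < 2:
            continue
        seg_t = np.arange(i1 - i0) / fs
        wave = tukey(i1 - i0, alpha=0.25) * np.sin(2 * np.pi * spec.burst_freq * seg_t + ph)
        for ci in range(recording.n_channels):
            out.samples[ci, i0:i1] += spec.burst_amp_factor * rms[ci] * wave
        intervals.append((i0 / fs, i1 / fs))
    merged = _merge_time_intervals(intervals)
    gt = GroundTruth(
        artifact_intervals={lb: list(merged) for lb in recording.channel_labels}
    )
    return out, gt


# ---------------------------------------------------------------------------
# Full sessions
# ---------------------------------------------------------------------------

def _coherence_mixing_weight(
    target: float,
    coupling: CouplingSpec,
    theta_band: tuple[float, float],
    n: int,
    fs: float,
) -> float:
    """Shared-theta power fraction lambda achieving the coherence target.

    With per-channel theta ``sqrt(lam) s + sqrt(1 - lam) n_i`` (all unit
    power) on top of an independent 1/f floor, the theta-band coherence is
    ``lam^2 (P_t / (P_t + N))^2``; invert for lam and clamp to [0, 1].
    """
    p_theta = coupling.theta_amp**2 / 2.0
    if p_theta == 0:
        return 0.0
    noise_band = coupling.noise_amp**2 * pink_band_fraction(
        n, fs, coupling.noise_exponent, *theta_band
    )
    lam = np.sqrt(target) * (p_theta + noise_band) / p_theta
    return float(min(1.0, lam))


def _coupled_segment(
    coupling: CouplingSpec,
    coherence: float,
    theta_bandwidth: float,
    duration: float,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Two-channel coupled segment with the requested theta coherence.

    Theta here is a narrowband stochastic process (bandpassed white noise
    around ``f_theta``): two deterministic sinusoids are always perfectly
    coherent, so a sub-unity coherence target needs a stochastic theta. The
    gamma envelope follows each channel's own instantaneous theta phase.
    """
    n = int(round(duration * fs))
    f_lo = coupling.f_theta - theta_bandwidth / 2.0
    f_hi = coupling.f_theta + theta_bandwidth / 2.0
    lam = _coherence_mixing_weight(coherence, coupling, (f_lo, f_hi), n, fs)
    shared = _narrowband_theta(coupling, theta_bandwidth, n, fs, rng)
    theta_rms = coupling.theta_amp / np.sqrt(2.0)
    chans = np.empty((2, n))
    for ci in range(2):
        own = _narrowband_theta(coupling, theta_bandwidth, n, fs, rng)
        theta = theta_rms * (np.sqrt(lam) * shared + np.sqrt(1.0 - lam) * own)
        chans[ci] = _stochastic_channel(coupling, theta, fs, rng)
    return chans


def generate_session(spec: SessionSpec) -> tuple[Recording, EventTable, GroundTruth]:
    """Full two-channel session: baseline, trials, platform rests, artifacts.

    Segment layout along time: ``pre_maze | trial_1 swim | trial_1 platform |
    trial_2 swim | ...``. Each trial contributes a ``trial_start`` event at
    the start of its swim segment and a ``platform_reach`` event at its end.
    Bit-identical output for identical specs (including seed).
    """
    rng = np.random.default_rng(spec.seed)
    coupling = spec.resolved_coupling()
    coherence = spec.resolved_coherence()
    durations = spec.resolved_trial_durations()
    for cs in coupling.values():
        if cs.f_gamma >= spec.fs / 2.0:
            raise ValueError("f_gamma must be below Nyquist")

    segments: list[tuple[str, int | None, float]] = [("pre_maze", None, spec.pre_maze_duration)]
    for tid, d in enumerate(durations, start=1):
        segments.append(("maze", tid, d))
        segments.append(("platform", tid, spec.platform_duration))

    parts = []
    rows = []
    t_cursor = 0.0
    for phase, tid, dur in segments:
        parts.append(
            _coupled_segment(
                coupling[phase], coherence[phase], spec.theta_bandwidth, dur, spec.fs, rng
            )
        )
        if phase == "maze":
            rows.append((tid, "trial_start", t_cursor))
            rows.append((tid, "platform_reach", t_cursor + dur))
        t_cursor += dur
    samples = np.concatenate(parts, axis=1)
    recording = Recording(samples, spec.fs, spec.channel_labels)
    events = EventTable.from_rows(rows)

    gt = GroundTruth(
        artifact_intervals={lb: [] for lb in spec.channel_labels},
        phase_coupling=coupling,
        theta_coherence=coherence,
    )
    if spec.artifact_spec is not None and spec.artifact_spec.rate > 0:
        recording, art_gt = inject_artifacts(
            recording, spec.artifact_spec, seed=int(rng.integers(2**31))
        )
        gt.artifact_intervals = art_gt.artifact_intervals
    return recording, events, gt
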