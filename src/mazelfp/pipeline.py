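"""End-to-end session analysis: scrub -> epoch -> spectra -> coupling -> stats.

``run_pipeline`` turns one session (recording + event table) into a
machine-readable report: per-phase peak-theta PSD per channel, per-phase
peak-theta coherence, optional comodulograms / surrogate z matrices for the
four channel pairings, and the recovered-signal summary. Everything is
deterministic given the configuration and seed.

``phase_contrast_cohort`` repeats the analysis over a cohort of synthetic
sessions and runs the one-way ANOVA across task phases on the per-session
phase summaries, mirroring how per-animal values feed group statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import artifacts, crossfreq, synthetic
from . import spectral as sp
from .behavior import simulate_trial_logs
from .io import EventTable, Epoch, Recording, decimate, extract_epochs, write_recording
from .stats import AnovaResult, one_way_anova

__all__ = ["RunConfig", "run_pipeline", "phase_contrast_cohort", "demo_dataset"]

PHASES = ("pre_maze", "maze", "platform")


@dataclass(frozen=True)
class RunConfig:
    """All pipeline constants in one place."""

    maze_window: float = 4.0
    pre_maze_duration: float = 60.0
    platform_duration: float = 15.0
    scrub_window_s: float = 0.25
    k_mad: float = 6.0
    spectral: sp.SpectralParams = sp.SpectralParams()
    grid: crossfreq.BandGrid = crossfreq.BandGrid()
    theta_band: tuple[float, float] = sp.THETA_BAND
    target_fs: float | None = None  # decimate before analysis when set
    compute_comodulograms: bool = False
    compute_zscores: bool = False
    n_surrogates: int = 100
    seed: int = 0
    # pre-maze baseline is split into pseudo-trials of this length so the
    # single baseline epoch contributes several observations like the trials do
    baseline_split_s: float = 15.0


def _clean_windows_for_epoch(
    epoch: Epoch,
    fs: float,
    params: sp.SpectralParams,
    mask: artifacts.ArtifactMask,
    channel: str,
) -> list[tuple[int, int]]:
    sl = epoch.sample_slice(fs)
    rel = sp.spectral_windows(sl.stop - sl.start, fs, params)
    absolute = [(s + sl.start, e + sl.start) for s, e in rel]
    return artifacts.mask_windows(mask, absolute, channel)


def _epoch_psd_peak(
    x: np.ndarray,
    epoch: Epoch,
    fs: float,
    cfg: RunConfig,
    mask: artifacts.ArtifactMask,
    channel: str,
) -> sp.PSDResult | None:
    windows = _clean_windows_for_epoch(epoch, fs, cfg.spectral, mask, channel)
    if not windows:
        return None
    psd = sp.multitaper_psd(x, fs, cfg.spectral, windows)
    sl = epoch.sample_slice(fs)
    clean = ~mask.boolean(channel)[sl]
    seg = x[sl][clean]
    if seg.size == 0 or not np.any(seg):
        return None
    return sp.rms_normalize(psd, seg)


@dataclass
class SessionReport:
    scrub: artifacts.ScrubReport
    psd_peaks: dict[tuple[str, str], sp.BandPeak]  # (phase, channel)
    coherence_peaks: dict[str, sp.BandPeak]  # phase
    comodulograms: dict[tuple[str, str, str], crossfreq.Comodulogram] = field(
        default_factory=dict
    )  # (phase, phase_channel, amp_channel)
    zscores: dict[tuple[str, str, str], crossfreq.ZComodulogram] = field(default_factory=dict)
    n_short_maze_epochs: int = 0

    def to_jsonable(self) -> dict:
        out: dict = {
            "scrub": {
                "total_seconds": self.scrub.total_seconds,
                "recovered": dict(self.scrub.recovered),
            },
            "psd_peaks": {
                f"{ph}/{ch}": {"freq_hz": p.freq, "value": p.value}
                for (ph, ch), p in self.psd_peaks.items()
            },
            "coherence_peaks": {
                ph: {"freq_hz": p.freq, "value": p.value}
                for ph, p in self.coherence_peaks.items()
            },
            "n_short_maze_epochs": self.n_short_maze_epochs,
        }
        if self.comodulograms:
            out["comodulogram_peaks"] = {
                f"{ph}/{pc}->{ac}": {
                    "phase_freq_hz": c.argmax_freqs()[0],
                    "amp_freq_hz": c.argmax_freqs()[1],
                    "max_mi": float(c.mi.max()),
                }
                for (ph, pc, ac), c in self.comodulograms.items()
            }
        if self.zscores:
            out["z_max"] = {
                f"{ph}/{pc}->{ac}": float(zc.z.max())
                for (ph, pc, ac), zc in self.zscores.items()
            }
        return out


def _split_baseline(epoch: Epoch, split_s: float) -> list[Epoch]:
    """Cut the single pre-maze epoch into equal pseudo-trials."""
    n = max(1, int(epoch.duration // split_s))
    edges = np.linspace(epoch.t_start, epoch.t_start + n * split_s, n + 1)
    return [
        Epoch("pre_maze", None, float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])
    ]


def run_pipeline(
    recording: Recording,
    events: EventTable,
    config: RunConfig = RunConfig(),
    out_dir: str | Path | None = None,
) -> SessionReport:
    """Analyze one session; optionally write the report under ``out_dir``."""
    if config.target_fs is not None:
        recording = decimate(recording, config.target_fs)
    fs = recording.fs
    epochs = extract_epochs(
        recording,
        events,
        maze_window=config.maze_window,
        platform_duration=config.platform_duration,
        pre_maze_duration=config.pre_maze_duration,
    )
    mask = artifacts.detect_artifacts(
        recording.samples,
        fs,
        window_s=config.scrub_window_s,
        k_mad=config.k_mad,
        channel_labels=recording.channel_labels,
    )
    scrub = artifacts.recovered_fraction(mask)

    phase_epochs: dict[str, list[Epoch]] = {}
    for ph in PHASES:
        eps = epochs.by_phase(ph)
        if ph == "pre_maze" and eps:
            eps = _split_baseline(eps[0], config.baseline_split_s)
        phase_epochs[ph] = eps

    psd_peaks: dict[tuple[str, str], sp.BandPeak] = {}
    coherence_peaks: dict[str, sp.BandPeak] = {}
    for ph, eps in phase_epochs.items():
        for ch in recording.channel_labels:
            x = recording.channel(ch)
            per_epoch = [
                p for e in eps if (p := _epoch_psd_peak(x, e, fs, config, mask, ch)) is not None
            ]
            if not per_epoch:
                continue
            mean_power = np.mean([p.power for p in per_epoch], axis=0)
            avg = sp.PSDResult(
                freqs=per_epoch[0].freqs,
                power=mean_power,
                n_windows=sum(p.n_windows for p in per_epoch),
                normalization="rms",
            )
            psd_peaks[(ph, ch)] = sp.peak_in_band(avg, config.theta_band)
        # coherence pools clean windows across the phase's epochs
        ch_a, ch_b = recording.channel_labels[:2]
        pooled = []
        for e in eps:
            wa = _clean_windows_for_epoch(e, fs, config.spectral, mask, ch_a)
            wb = set(_clean_windows_for_epoch(e, fs, config.spectral, mask, ch_b))
            pooled.extend(w for w in wa if w in wb)
        if len(pooled) * config.spectral.n_tapers >= 2:
            coh = sp.multitaper_coherence(
                recording.channel(ch_a), recording.channel(ch_b), fs, config.spectral, pooled
            )
            coherence_peaks[ph] = sp.peak_in_band(coh, config.theta_band)

    report = SessionReport(
        scrub=scrub,
        psd_peaks=psd_peaks,
        coherence_peaks=coherence_peaks,
        n_short_maze_epochs=len(epochs.by_phase("maze", include_short=True))
        - len(epochs.by_phase("maze")),
    )

    if config.compute_comodulograms or config.compute_zscores:
        flagged = {ch: mask.boolean(ch) for ch in recording.channel_labels}
        for ph, eps in phase_epochs.items():
            in_phase = np.zeros(recording.n_samples, dtype=bool)
            for e in eps:
                in_phase[e.sample_slice(fs)] = True
            for pc in recording.channel_labels:
                for ac in recording.channel_labels:
                    clean = in_phase & ~flagged[pc] & ~flagged[ac]
                    key = (ph, pc, ac)
                    if config.compute_zscores:
                        zc = crossfreq.surrogate_zscores(
                            recording.channel(pc),
                            recording.channel(ac),
                            fs,
                            config.grid,
                            n_surrogates=config.n_surrogates,
                            seed=config.seed,
                            clean=clean,
                        )
                        report.zscores[key] = zc
                        report.comodulograms[key] = crossfreq.Comodulogram(zc.mi, config.grid)
                    else:
                        report.comodulograms[key] = crossfreq.comodulogram(
                            recording.channel(pc),
                            recording.channel(ac),
                            fs,
                            config.grid,
                            clean=clean,
                        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "session_report.json").write_text(
            json.dumps(report.to_jsonable(), indent=2, sort_keys=True) + "\n"
        )
        for (ph, pc, ac), c in report.comodulograms.items():
            pd.DataFrame(
                c.mi, index=list(c.grid.amp_freqs), columns=list(c.grid.phase_freqs)
            ).to_csv(out_dir / f"comodulogram_{ph}_{pc}_to_{ac}.csv")
        for (ph, pc, ac), zc in report.zscores.items():
            pd.DataFrame(
                zc.z, index=list(zc.grid.amp_freqs), columns=list(zc.grid.phase_freqs)
            ).to_csv(out_dir / f"zscores_{ph}_{pc}_to_{ac}.csv")
    return report


def phase_contrast_cohort(
    n_sessions: int = 5,
    base_spec: synthetic.SessionSpec | None = None,
    config: RunConfig = RunConfig(),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, AnovaResult]]:
    """Analyze a cohort of synthetic sessions and test phase contrasts.

    Each session gets its own sub-seed; the per-session per-phase peak-theta
    PSD (first channel) and coherence feed a one-way ANOVA across the three
    task phases. Returns the tidy per-session table and the ANOVA per metric.
    """
    base_spec = base_spec or synthetic.SessionSpec()
    rows = []
    for i in range(n_sessions):
        spec = replace(base_spec, seed=seed * 10_000 + i)
        rec, events, _ = synthetic.generate_session(spec)
        cfg = replace(
            config,
            pre_maze_duration=spec.pre_maze_duration,
            platform_duration=spec.platform_duration,
        )
        report = run_pipeline(rec, events, cfg)
        for ph in PHASES:
            row = {"session": i, "phase": ph}
            for ch in rec.channel_labels:
                if (ph, ch) in report.psd_peaks:
                    row[f"psd_{ch}"] = report.psd_peaks[(ph, ch)].value
            if ph in report.coherence_peaks:
                row["coherence"] = report.coherence_peaks[ph].value
            rows.append(row)
    df = pd.DataFrame(rows)
    anovas: dict[str, AnovaResult] = {}
    for metric in [c for c in df.columns if c not in ("session", "phase")]:
        groups = [df.loc[df["phase"] == ph, metric].dropna().to_numpy() for ph in PHASES]
        if all(g.size >= 2 for g in groups):
            anovas[metric] = one_way_anova(groups)
    return df, anovas


def demo_dataset(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a small self-contained demo session (~70 s, 2 channels).

    Emits the recording (float32 + JSON sidecar), the event table and
    ground-truth artifact intervals, plus synthetic trial logs; used by the
    docs and the analysis drivers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = synthetic.SessionSpec(
        fs=500.0,
        pre_maze_duration=20.0,
        n_trials=2,
        trial_durations=10.0,
        platform_duration=10.0,
        artifact_spec=synthetic.ArtifactSpec(rate=0.05),
        seed=seed,
    )
    rec, events, gt = synthetic.generate_session(spec)
    paths = {
        "recording": out_dir / "demo_recording.bin",
        "events": out_dir / "demo_events.csv",
        "ground_truth": out_dir / "demo_ground_truth.json",
        "trial_logs": out_dir / "demo_trials.csv",
    }
    write_recording(rec, paths["recording"])
    events.to_csv(paths["events"])
    paths["ground_truth"].write_text(
        json.dumps(
            {
                "artifact_intervals": gt.artifact_intervals,
                "theta_coherence": gt.theta_coherence,
                "fs_hz": spec.fs,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    simulate_trial_logs(n_sessions=2, trials_per_session=2, n_rats=2, seed=seed).to_csv(
        paths["trial_logs"], index=False
    )
    return paths
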