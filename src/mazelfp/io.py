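"""Recording container, file round-trip, decimation and task-phase epoching.

A session is a continuous multichannel LFP recording accompanied by an event
table (per-trial ``trial_start`` / ``platform_reach`` timestamps taken from
video synchronization). Epoching cuts three kinds of labeled segments out of
the recording:

* ``pre_maze``  -- the baseline minute before the first trial,
* ``maze``      -- the last seconds of swimming before the platform is reached,
* ``platform``  -- the consolidation period on the platform.

All epoch boundaries are half-open ``[t_start, t_end)`` in seconds;
conversion to sample indices uses ``floor(t * fs)`` with 0-based indexing, so
re-assembling non-overlapping epochs never duplicates a sample.

On disk a recording is raw little-endian float32 (channel-major) next to a
JSON sidecar carrying ``fs_hz``, shape and channel labels; tiny fixtures can
also round-trip through CSV.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal

__all__ = [
    "Recording",
    "EventTable",
    "Epoch",
    "EpochSet",
    "read_recording",
    "write_recording",
    "read_recording_csv",
    "write_recording_csv",
    "decimate",
    "extract_epochs",
]

PHASES = ("pre_maze", "maze", "platform")
EVENT_TYPES = ("trial_start", "platform_reach")


@dataclass
class Recording:
    """Multichannel continuous signal.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)`` in signal units (µV nominal).
    fs
        Sampling rate in Hz.
    channel_labels
        One unique label per channel, e.g. ``("dCA1", "dlSTR")``.
    """

    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.channel_labels = tuple(self.channel_labels)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (n_channels, n_samples) array")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Total duration in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D sample vector for a channel label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}; have {self.channel_labels}") from None
        return self.samples[idx]

    def copy(self) -> "Recording":
        return Recording(self.samples.copy(), self.fs, self.channel_labels)


class EventTable:
    """Per-trial task events: ``trial_start`` and ``platform_reach`` times.

    Wraps a DataFrame with columns ``trial_id`` (int), ``event`` (str) and
    ``t_s`` (float, seconds from recording start). Within a trial, the
    platform-reach time must be strictly after the trial start.
    """

    COLUMNS = ("trial_id", "event", "t_s")

    def __init__(self, df: pd.DataFrame):
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["trial_id"] = df["trial_id"].astype(int)
        df["t_s"] = df["t_s"].astype(float)
        bad = set(df["event"]) - set(EVENT_TYPES)
        if bad:
            raise ValueError(f"unknown event types: {sorted(bad)}")
        for tid, sub in df.groupby("trial_id"):
            if not sub["t_s"].is_monotonic_increasing:
                raise ValueError(f"trial {tid}: event times must be non-decreasing")
            starts = sub.loc[sub["event"] == "trial_start", "t_s"]
            reaches = sub.loc[sub["event"] == "platform_reach", "t_s"]
            if len(starts) != 1 or len(reaches) != 1:
                raise ValueError(f"trial {tid}: need exactly one start and one platform_reach")
            if reaches.iloc[0] <= starts.iloc[0]:
                raise ValueError(f"trial {tid}: platform_reach must follow trial_start")
        self.df = df.sort_values(["trial_id", "t_s"], kind="stable").reset_index(drop=True)

    @classmethod
    def from_rows(cls, rows) -> "EventTable":
        """Build from an iterable of ``(trial_id, event, t_s)`` tuples."""
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    @property
    def trial_ids(self) -> list[int]:
        return sorted(self.df["trial_id"].unique().tolist())

    def time_of(self, trial_id: int, event: str) -> float:
        sel = self.df[(self.df["trial_id"] == trial_id) & (self.df["event"] == event)]
        if sel.empty:
            raise KeyError(f"no {event!r} for trial {trial_id}")
        return float(sel["t_s"].iloc[0])

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "EventTable":
        return cls(pd.read_csv(path))

    def __eq__(self, other) -> bool:
        return isinstance(other, EventTable) and self.df.equals(other.df)

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class Epoch:
    """Half-open labeled segment ``[t_start, t_end)`` of a recording."""

    phase: str
    trial_id: int | None
    t_start: float
    t_end: float
    short: bool = False  # maze epoch truncated by an early platform reach

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def sample_slice(self, fs: float) -> slice:
        """0-based half-open sample slice via floor(t * fs)."""
        return slice(int(np.floor(self.t_start * fs)), int(np.floor(self.t_end * fs)))


@dataclass
class EpochSet:
    epochs: list[Epoch] = field(default_factory=list)

    def by_phase(self, phase: str, include_short: bool = False) -> list[Epoch]:
        return [
            e for e in self.epochs if e.phase == phase and (include_short or not e.short)
        ]

    def __iter__(self):
        return iter(self.epochs)

    def __len__(self) -> int:
        return len(self.epochs)


# ---------------------------------------------------------------------------
# File I/O: raw float32 + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(recording: Recording, path) -> None:
    """Write samples as little-endian float32 with a JSON metadata sidecar."""
    if not np.all(np.isfinite(recording.samples)):
        raise ValueError("refusing to write non-finite samples")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    recording.samples.astype("<f4").tofile(path)
    meta = {
        "fs_hz": recording.fs,
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
        "channel_labels": list(recording.channel_labels),
        "dtype": "float32",
        "byte_order": "little",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if meta.get("dtype") != "float32" or meta.get("byte_order") != "little":
        raise ValueError("unsupported sample encoding in sidecar")
    fs = float(meta["fs_hz"])
    if fs <= 0:
        raise ValueError(f"sidecar fs_hz must be positive, got {fs}")
    raw = np.fromfile(path, dtype="<f4")
    n_ch, n_s = int(meta["n_channels"]), int(meta["n_samples"])
    if raw.size != n_ch * n_s:
        raise ValueError(
            f"file holds {raw.size} samples, sidecar promises {n_ch}x{n_s}"
        )
    return Recording(raw.reshape(n_ch, n_s).astype(float), fs, tuple(meta["channel_labels"]))


def write_recording_csv(recording: Recording, path) -> None:
    """CSV export (one column per channel) for tiny text fixtures."""
    pd.DataFrame(
        recording.samples.T, columns=list(recording.channel_labels)
    ).to_csv(path, index=False)


def read_recording_csv(path, fs: float) -> Recording:
    df = pd.read_csv(path)
    return Recording(df.to_numpy().T, fs, tuple(df.columns))


# ---------------------------------------------------------------------------
# Decimation
# ---------------------------------------------------------------------------

def decimate(recording: Recording, target_fs: float) -> Recording:
    """Anti-alias filter and downsample to ``target_fs`` (integer factor only).

    Large factors are applied in stages of at most 10, the standard practice
    for FIR decimation stability.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    factor = recording.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"decimation factor {factor:g} is not an integer (fs={recording.fs}, target={target_fs})"
        )
    factor = int(round(factor))
    if factor == 1:
        return recording.copy()
    x = recording.samples
    remaining = factor
    while remaining > 1:
        q = remaining
        if q > 10:  # split large factors into stages
            for d in range(10, 1, -1):
                if remaining % d == 0:
                    q = d
                    break
            else:
                q = remaining
        x = scipy.signal.decimate(x, q, ftype="fir", zero_phase=True, axis=-1)
        remaining //= q
    return Recording(x, target_fs, recording.channel_labels)


# ---------------------------------------------------------------------------
# Epoch extraction
# ---------------------------------------------------------------------------

def extract_epochs(
    recording: Recording,
    events: EventTable,
    maze_window: float = 4.0,
    platform_duration: float = 15.0,
    pre_maze_duration: float = 60.0,
) -> EpochSet:
    """Cut pre-maze / maze / platform epochs out of a session.

    The maze epoch of each trial is the ``maze_window`` seconds immediately
    before the platform is reached; if the rat reached the platform sooner
    than that after the trial start, the epoch is truncated to the trial
    bounds and flagged ``short`` (flagged epochs are excluded from spectral
    averaging by default). Platform epochs are clipped to the recording end
    with a warning.
    """
    epochs = [Epoch("pre_maze", None, 0.0, min(pre_maze_duration, recording.duration))]
    for tid in events.trial_ids:
        t0 = events.time_of(tid, "trial_start")
        reach = events.time_of(tid, "platform_reach")
        m_start = reach - maze_window
        short = False
        if m_start < t0:
            m_start, short = t0, True
        epochs.append(Epoch("maze", tid, m_start, reach, short=short))
        p_end = reach + platform_duration
        if p_end > recording.duration + 1e-9:
            warnings.warn(
                f"trial {tid}: platform epoch clipped to recording end "
                f"({p_end:.2f} s > {recording.duration:.2f} s)",
                stacklevel=2,
            )
            p_end = recording.duration
        epochs.append(Epoch("platform", tid, reach, p_end))
    return EpochSet(epochs)
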