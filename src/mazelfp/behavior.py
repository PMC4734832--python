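"""Double-H water-maze trial scoring from zone-visit sequences.

A trial is summarized by the time to reach the goal arm and the platform,
and by two error counts derived from the ordered sequence of maze zones the
rat entered: an *initial* error is the first entry into each of the five
error zones; every further entry into an already-visited error zone is a
*repetitive* error. Hence ``initial = number of distinct error zones
entered`` (at most 5) and ``repetitive = total error-zone entries -
initial``.

Input is a pre-extracted zone sequence (video tracking is out of scope);
:func:`simulate_trial_logs` emits plausible logs with a configurable
learning curve for pipeline tests and the behavioral ANOVA demo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrialLog",
    "Latencies",
    "score_errors",
    "latencies",
    "simulate_trial_logs",
    "session_summary",
    "DEFAULT_ERROR_ZONES",
]

DEFAULT_ERROR_ZONES = frozenset({"E1", "E2", "E3", "E4", "E5"})


@dataclass
class TrialLog:
    """One trial's zone-entry sequence plus the key event times."""

    trial_id: int
    zone_sequence: list[tuple[float, str]]  # (entry time s, zone label)
    goal_arm_time: float | None = None
    platform_time: float | None = None
    error_zones: frozenset[str] = DEFAULT_ERROR_ZONES

    def __post_init__(self):
        self.error_zones = frozenset(self.error_zones)
        if len(self.error_zones) != 5:
            raise ValueError("exactly 5 error zones are required")
        times = [t for t, _ in self.zone_sequence]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("zone entry times must be non-decreasing")


@dataclass(frozen=True)
class Latencies:
    goal_arm: float | None  # seconds; None -> not reached
    platform: float | None

    @property
    def goal_reached(self) -> bool:
        return self.goal_arm is not None

    @property
    def platform_reached(self) -> bool:
        return self.platform is not None


def score_errors(
    log: TrialLog,
    known_zones: set[str] | None = None,
) -> tuple[int, int]:
    """(initial, repetitive) error counts for one trial.

    Consecutive duplicate zone labels collapse only when their entry times
    are identical (a double-logged entry); otherwise each entry counts.
    If ``known_zones`` is given, any unlisted label raises.
    """
    if known_zones is not None:
        valid = set(known_zones) | set(log.error_zones)
        unknown = {z for _, z in log.zone_sequence} - valid
        if unknown:
            raise ValueError(f"unknown zone labels: {sorted(unknown)}")
    entries: list[tuple[float, str]] = []
    for t, z in log.zone_sequence:
        if entries and entries[-1] == (t, z):
            continue  # identical time+label: duplicate log line
        entries.append((t, z))
    error_entries = [z for _, z in entries if z in log.error_zones]
    initial = len(set(error_entries))
    repetitive = len(error_entries) - initial
    return initial, repetitive


def latencies(log: TrialLog, trial_start: float = 0.0) -> Latencies:
    """Goal-arm and platform latencies in seconds from the trial start."""
    for name, t in (("goal_arm", log.goal_arm_time), ("platform", log.platform_time)):
        if t is not None and t < trial_start:
            raise ValueError(f"{name} time {t} precedes trial start {trial_start}")
    if (
        log.goal_arm_time is not None
        and log.platform_time is not None
        and log.platform_time < log.goal_arm_time
    ):
        raise ValueError("platform cannot be reached before the goal arm")
    goal = None if log.goal_arm_time is None else log.goal_arm_time - trial_start
    plat = None if log.platform_time is None else log.platform_time - trial_start
    return Latencies(goal_arm=goal, platform=plat)


def simulate_trial_logs(
    n_sessions: int = 4,
    trials_per_session: int = 4,
    n_rats: int = 8,
    groups: tuple[str, ...] = ("wireless", "sham"),
    initial_error_rate: float = 3.0,
    learning_factor: float = 0.5,
    base_latency: float = 40.0,
    latency_floor: float = 8.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic learning-curve behavior for the session x group ANOVA demo.

    Error counts are Poisson with a mean decaying by ``learning_factor`` per
    session; latencies decay exponentially toward ``latency_floor`` with
    lognormal noise. Both groups share the same learning parameters (the
    recording hardware does not affect behavior), so the group effect is
    null by construction. Returns one row per trial with scored errors and
    latencies (computed by :func:`score_errors` / :func:`latencies` on the
    generated logs, not assigned directly).
    """
    rng = np.random.default_rng(seed)
    error_zone_list = sorted(DEFAULT_ERROR_ZONES)
    rows = []
    for group in groups:
        for rat in range(n_rats):
            for session in range(1, n_sessions + 1):
                lam = initial_error_rate * learning_factor ** (session - 1)
                for trial in range(1, trials_per_session + 1):
                    n_err = int(rng.poisson(lam))
                    zones = [error_zone_list[i] for i in rng.integers(0, 5, n_err)]
                    goal_t = latency_floor + (base_latency - latency_floor) * (
                        learning_factor ** (session - 1)
                    ) * rng.lognormal(0.0, 0.3)
                    plat_t = goal_t + rng.uniform(1.0, 4.0)
                    times = np.sort(rng.uniform(0.0, goal_t, n_err))
                    log = TrialLog(
                        trial_id=trial,
                        zone_sequence=list(zip(times.tolist(), zones)),
                        goal_arm_time=goal_t,
                        platform_time=plat_t,
                    )
                    initial, repetitive = score_errors(log)
                    lat = latencies(log)
                    rows.append(
                        {
                            "group": group,
                            "rat": f"{group}_{rat}",
                            "session": session,
                            "trial": trial,
                            "initial_errors": initial,
                            "repetitive_errors": repetitive,
                            "goal_arm_latency": lat.goal_arm,
                            "platform_latency": lat.platform,
                        }
                    )
    return pd.DataFrame(rows)


def session_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM of each behavioral metric per session per group."""
    metrics = ["initial_errors", "repetitive_errors", "goal_arm_latency", "platform_latency"]
    g = df.groupby(["group", "session"])[metrics]
    mean = g.mean().add_suffix("_mean")
    sem = g.sem().add_suffix("_sem")
    return mean.join(sem).reset_index()
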