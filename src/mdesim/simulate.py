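"""Weekly discrete event simulation of depressive-episode trajectories.

Each entity carries a fixed :class:`~mdesim.hazards.AttributeProfile`
and is followed over a 208-week horizon: a two-year run-in (weeks 1-104)
during which a single new episode onset occurs at a uniformly random
week, then two further years to the follow-up interview.  State
transitions are evaluated at week end: a depressed week ends with a
Bernoulli recovery draw at the complementary-log-log hazard (driven by
the cumulative weeks-depressed clock), a recovered week ends with a
Bernoulli recurrence draw at the profile's constant weekly log-odds.  A
recovery and a recurrence can never occur in the same week.

All randomness flows from a single integer seed.  Within a cohort, each
profile gets an independent substream seeded by ``(seed, profile_index)``
and each entity consumes one fixed row of that substream's uniform
matrix, so enlarging the cohort never reshuffles existing entities'
draws and two parameter sets evaluated at the same seed see identical
uniforms (common random numbers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .hazards import (
    AttributeProfile,
    RecoveryParameters,
    RecurrenceParameters,
    TimeConstants,
    enumerate_profiles,
    recovery_linear_predictor,
    recovery_probability,
    recurrence_linear_predictor,
    recurrence_probability,
)

__all__ = [
    "Episode",
    "SimulationConfig",
    "TrajectoryRecord",
    "draw_onset_week",
    "simulate_entity",
    "simulate_cohort",
    "simulate_durations",
    "draw_recurrence_person_weeks",
]


class Episode(NamedTuple):
    start_week: int
    end_week: int
    censored: bool


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce a simulated cohort bit-for-bit."""

    recovery: RecoveryParameters
    recurrence: RecurrenceParameters
    n_entities_per_profile: int = 100
    time: TimeConstants = field(default_factory=TimeConstants)
    seed: int = 0
    reset_clock_on_recurrence: bool = False

    def __post_init__(self) -> None:
        if self.n_entities_per_profile < 1:
            raise ValueError("n_entities_per_profile must be positive")


@dataclass
class TrajectoryRecord:
    """One entity's simulated weekly depression history."""

    profile: AttributeProfile
    onset_week: int
    depressed: np.ndarray  # bool, index w-1 holds week w (1-based weeks)
    episodes: list[Episode]

    @property
    def cumulative_weeks_depressed(self) -> int:
        return int(self.depressed.sum())


def draw_onset_week(rng: np.random.Generator, time: TimeConstants | None = None) -> int:
    """One onset week, discrete uniform on {1, ..., onset window}."""
    time = time or TimeConstants()
    return int(rng.integers(1, time.onset_window_weeks + 1))


def _recovery_prob_by_clock(
    profile: AttributeProfile, params: RecoveryParameters, horizon: int
) -> np.ndarray:
    """Weekly recovery probability indexed by episode-clock value 1..horizon."""
    clock = np.arange(1, horizon + 1)
    return np.asarray(recovery_probability(recovery_linear_predictor(profile, clock, params)))


def _run_weekly_loop(
    onset: np.ndarray,
    uniforms: np.ndarray,
    p_rec_rows: np.ndarray,
    p_recur: np.ndarray,
    reset_clock_on_recurrence: bool,
) -> np.ndarray:
    """Advance n entities through the weekly loop.

    ``uniforms[i, w-1]`` is entity i's transition draw at the end of
    week w; ``p_rec_rows[i, c-1]`` its recovery probability at episode
    clock c; ``p_recur[i]`` its constant weekly recurrence probability.
    Returns the (n, horizon) boolean depressed matrix.
    """
    n, horizon = uniforms.shape
    state = np.zeros(n, dtype=np.int8)  # 0 pre-onset, 1 depressed, 2 recovered
    clock = np.zeros(n, dtype=np.int64)
    dep = np.zeros((n, horizon), dtype=bool)
    rows = np.arange(n)

    for w in range(1, horizon + 1):
        state[(state == 0) & (onset == w)] = 1
        depressed = state == 1
        recovered = state == 2
        u = uniforms[:, w - 1]
        if depressed.any():
            clock[depressed] += 1
            dep[depressed, w - 1] = True
            recovers = depressed & (u < p_rec_rows[rows, clock - 1])
            state[recovers] = 2
        if recovered.any():
            recurs = recovered & (u < p_recur)
            if recurs.any():
                state[recurs] = 1
                if reset_clock_on_recurrence:
                    clock[recurs] = 0
    return dep


def _simulate_profile(
    profile: AttributeProfile,
    onset: np.ndarray,
    uniforms: np.ndarray,
    config: SimulationConfig,
) -> np.ndarray:
    """Weekly loop for n entities sharing one profile."""
    n, horizon = uniforms.shape
    p_rec = _recovery_prob_by_clock(profile, config.recovery, horizon)
    p_recur = recurrence_probability(recurrence_linear_predictor(profile, config.recurrence))
    return _run_weekly_loop(
        onset,
        uniforms,
        np.broadcast_to(p_rec, (n, horizon)),
        np.full(n, p_recur),
        config.reset_clock_on_recurrence,
    )


def _episodes_from_weeks(dep: np.ndarray) -> list[Episode]:
    """Maximal runs of depressed weeks; the final run is censored at the horizon."""
    (weeks,) = np.nonzero(dep)
    episodes: list[Episode] = []
    if weeks.size == 0:
        return episodes
    weeks = weeks + 1  # to 1-based
    breaks = np.nonzero(np.diff(weeks) > 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [weeks.size - 1]))
    horizon = dep.size
    for s, e in zip(starts, ends):
        end_week = int(weeks[e])
        episodes.append(Episode(int(weeks[s]), end_week, end_week == horizon))
    return episodes


def simulate_entity(
    profile: AttributeProfile, config: SimulationConfig, rng: np.random.Generator
) -> TrajectoryRecord:
    """Simulate a single entity, drawing onset and weekly transitions from *rng*."""
    horizon = config.time.horizon_weeks
    onset = np.array([draw_onset_week(rng, config.time)])
    uniforms = rng.random((1, horizon))
    dep = _simulate_profile(profile, onset, uniforms, config)[0]
    return TrajectoryRecord(profile, int(onset[0]), dep, _episodes_from_weeks(dep))


def _profile_stream(seed: int, profile_index: int) -> np.random.Generator:
    return np.random.default_rng([seed, profile_index])


def simulate_cohort(
    config: SimulationConfig,
    profiles: Sequence[AttributeProfile] | None = None,
) -> list[TrajectoryRecord]:
    """Simulate ``n_entities_per_profile`` trajectories for each profile.

    Defaults to the full 40-profile space.  Deterministic for a fixed
    seed and config; the uniform stream depends only on (seed, profile
    index, entity index), not on the hazard parameters, which makes the
    calibration objective a deterministic function of the parameters
    given the seed.
    """
    profiles = list(profiles) if profiles is not None else enumerate_profiles()
    horizon = config.time.horizon_weeks
    n = config.n_entities_per_profile

    # One uniform block per (profile, entity): column 0 drives onset,
    # the rest the weekly transitions.  All profiles then advance
    # through a single vectorised weekly loop.
    onset_all = np.empty(len(profiles) * n, dtype=np.int64)
    uniforms_all = np.empty((len(profiles) * n, horizon))
    p_rec_rows = np.empty((len(profiles) * n, horizon))
    p_recur_all = np.empty(len(profiles) * n)
    for pidx, profile in enumerate(profiles):
        rng = _profile_stream(config.seed, pidx)
        block = rng.random((n, horizon + 1))
        sl = slice(pidx * n, (pidx + 1) * n)
        onset_all[sl] = 1 + np.floor(block[:, 0] * config.time.onset_window_weeks).astype(np.int64)
        uniforms_all[sl] = block[:, 1:]
        p_rec_rows[sl] = _recovery_prob_by_clock(profile, config.recovery, horizon)
        p_recur_all[sl] = recurrence_probability(
            recurrence_linear_predictor(profile, config.recurrence)
        )
    dep_all = _run_weekly_loop(
        onset_all, uniforms_all, p_rec_rows, p_recur_all, config.reset_clock_on_recurrence
    )

    records: list[TrajectoryRecord] = []
    for pidx, profile in enumerate(profiles):
        for i in range(n):
            j = pidx * n + i
            records.append(
                TrajectoryRecord(
                    profile, int(onset_all[j]), dep_all[j], _episodes_from_weeks(dep_all[j])
                )
            )
    return records


def simulate_durations(
    profile: AttributeProfile,
    n: int,
    recovery: RecoveryParameters,
    max_weeks: int = 208,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-episode durations under the recovery hazard alone.

    Episodes start at week 1 with no recurrence; returns ``(duration,
    event)`` arrays where ``event`` is False for episodes still ongoing
    at ``max_weeks`` (right-censored at the stated duration).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    p_rec = _recovery_prob_by_clock(profile, recovery, max_weeks)
    u = rng.random((n, max_weeks))
    recovered = u < p_rec[None, :]
    first = np.argmax(recovered, axis=1)
    event = recovered.any(axis=1)
    duration = np.where(event, first + 1, max_weeks)
    return duration.astype(np.int64), event


def draw_recurrence_person_weeks(
    profile: AttributeProfile,
    params: RecurrenceParameters,
    n_weeks: int,
    rng: np.random.Generator,
) -> int:
    """Number of recurrence events in *n_weeks* simulated at-risk person-weeks."""
    p = recurrence_probability(recurrence_linear_predictor(profile, params))
    return int(rng.binomial(n_weeks, p))
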