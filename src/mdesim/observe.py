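"""NPHS-style observation layer: what a biennial survey sees of a trajectory.

The survey interviews each entity at the end of the run-in (week 104,
"baseline") and two years later (week 208, "follow-up").  At each
interview the instrument detects a past-year major depressive episode
when the entity was depressed at least ``min_weeks_positive`` weeks in
the 52-week window ending at the interview, and baseline-positive
respondents additionally report their weeks depressed in the past year,
collapsed into four ordered duration categories.  Records that are not
baseline-positive are flagged excluded, emulating an analysis file of
new-onset, baseline-positive episodes.

These measurements are the "flawed estimators" the calibration stage
must reproduce: consecutive positivity mixes episode persistence with
true recurrence, and weeks-in-past-year truncates episode duration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .hazards import AGE_GROUPS, AttributeProfile, TimeConstants, enumerate_profiles
from .simulate import TrajectoryRecord

__all__ = [
    "WEEKS_CATEGORIES",
    "ObservationRecord",
    "categorize_weeks",
    "weeks_depressed_in_window",
    "observe_cohort",
    "observations_to_frame",
    "summarize_by_profile",
    "category_distribution_by_age",
    "follow_up_response_rate",
]

#: Ordered weeks-depressed-in-past-year categories (inclusive bounds).
WEEKS_CATEGORIES: tuple[str, ...] = ("1-6", "7-12", "13-25", "26-52")
_CATEGORY_EDGES = (6, 12, 25, 52)


def categorize_weeks(weeks: int) -> str:
    """Collapse a 1..52 weeks-depressed count into the four ordered categories.

    The middle boundaries (7-12 and 13-25) are fixed by the survey
    analysis; the outer bounds 1-6 and 26-52 complete the partition.
    """
    if weeks < 1:
        raise ValueError("a past-year-positive respondent reports at least 1 week")
    if weeks > _CATEGORY_EDGES[-1]:
        raise ValueError(f"weeks depressed in past year cannot exceed {_CATEGORY_EDGES[-1]}")
    for label, hi in zip(WEEKS_CATEGORIES, _CATEGORY_EDGES):
        if weeks <= hi:
            return label
    raise AssertionError("unreachable")


def weeks_depressed_in_window(
    trajectory: TrajectoryRecord, interview_week: int, window: int
) -> int:
    """Depressed weeks in the closed window [interview_week - window + 1, interview_week]."""
    horizon = trajectory.depressed.size
    if interview_week > horizon:
        raise ValueError(f"interview week {interview_week} beyond horizon {horizon}")
    if window > interview_week:
        raise ValueError("window extends before the start of the simulation")
    return int(trajectory.depressed[interview_week - window : interview_week].sum())


@dataclass(frozen=True)
class ObservationRecord:
    """The survey's view of one entity."""

    profile: AttributeProfile
    baseline_positive: bool
    weeks_depressed_past_year: int
    weeks_category: str | None  # defined only when baseline_positive
    followup_positive: bool
    included: bool


def observe_cohort(
    trajectories: Sequence[TrajectoryRecord],
    time: TimeConstants | None = None,
    min_weeks_positive: int = 1,
) -> list[ObservationRecord]:
    """Apply both interviews and the inclusion filter to every trajectory.

    ``min_weeks_positive`` is the detection threshold of the instrument
    (default 1 depressed week in the past-year window; the underlying
    diagnostic instrument nominally requires a 2-week symptomatic spell,
    exposed here as the stricter setting).
    """
    time = time or TimeConstants()
    w = time.past_year_window_weeks
    out: list[ObservationRecord] = []
    for traj in trajectories:
        weeks_base = weeks_depressed_in_window(traj, time.baseline_week, w)
        weeks_follow = weeks_depressed_in_window(traj, time.followup_week, w)
        base_pos = weeks_base >= min_weeks_positive
        follow_pos = weeks_follow >= min_weeks_positive
        out.append(
            ObservationRecord(
                profile=traj.profile,
                baseline_positive=base_pos,
                weeks_depressed_past_year=weeks_base,
                weeks_category=categorize_weeks(weeks_base) if base_pos else None,
                followup_positive=follow_pos,
                included=base_pos,
            )
        )
    return out


def observations_to_frame(observations: Iterable[ObservationRecord]) -> pd.DataFrame:
    rows = [
        {
            "age_group": o.profile.age_group,
            "pain": int(o.profile.pain),
            "smoker": int(o.profile.smoker),
            "childhood_stressor": int(o.profile.childhood_stressor),
            "baseline_positive": int(o.baseline_positive),
            "weeks_depressed_past_year": o.weeks_depressed_past_year,
            "weeks_category": o.weeks_category,
            "followup_positive": int(o.followup_positive),
            "included": int(o.included),
        }
        for o in observations
    ]
    return pd.DataFrame(rows)


def _profile_key(p: AttributeProfile) -> tuple:
    return (p.age_index, int(p.pain), int(p.smoker), int(p.childhood_stressor))


def summarize_by_profile(observations: Iterable[ObservationRecord]) -> pd.DataFrame:
    """Per-profile summary over *included* records: one row per profile (40 max).

    Columns: profile attributes, ``n_included``, the follow-up
    positivity proportion and the four weeks-category proportions.
    Profiles with no included record are flagged ``empty`` with NaN
    proportions (they contribute nothing to a calibration objective).
    """
    obs = list(observations)
    rows = []
    by_key: dict[tuple, list[ObservationRecord]] = {}
    for o in obs:
        if o.included:
            by_key.setdefault(_profile_key(o.profile), []).append(o)
    for profile in enumerate_profiles():
        members = by_key.get(_profile_key(profile), [])
        n = len(members)
        row = {
            "age_group": profile.age_group,
            "pain": int(profile.pain),
            "smoker": int(profile.smoker),
            "childhood_stressor": int(profile.childhood_stressor),
            "n_included": n,
            "empty": n == 0,
        }
        if n:
            row["p_followup_positive"] = sum(o.followup_positive for o in members) / n
            for cat in WEEKS_CATEGORIES:
                row[f"p_weeks_{cat}"] = sum(o.weeks_category == cat for o in members) / n
        else:
            row["p_followup_positive"] = np.nan
            for cat in WEEKS_CATEGORIES:
                row[f"p_weeks_{cat}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def category_distribution_by_age(
    observations: Iterable[ObservationRecord],
) -> pd.DataFrame:
    """Weeks-category distribution pooled within each age group (included records).

    Returns a 5 x 4 frame indexed by age group; rows sum to 1 where the
    group has any included record, NaN otherwise.
    """
    counts = {age: dict.fromkeys(WEEKS_CATEGORIES, 0) for age in AGE_GROUPS}
    for o in observations:
        if o.included and o.weeks_category is not None:
            counts[o.profile.age_group][o.weeks_category] += 1
    rows = {}
    for age in AGE_GROUPS:
        total = sum(counts[age].values())
        rows[age] = (
            {c: counts[age][c] / total for c in WEEKS_CATEGORIES}
            if total
            else dict.fromkeys(WEEKS_CATEGORIES, np.nan)
        )
    return pd.DataFrame.from_dict(rows, orient="index")[list(WEEKS_CATEGORIES)]


def follow_up_response_rate(cohort_size: int, nonrespondents: int) -> float:
    """Longitudinal follow-up response rate, in percent.

    Members who left the sampling frame (deceased or institutionalized)
    were followed until exit and therefore count as successes; the rate
    is simply the share of the original cohort never classified
    non-respondent: ``100 * (cohort_size - nonrespondents) / cohort_size``.
    """
    if cohort_size <= 0 or nonrespondents < 0 or nonrespondents > cohort_size:
        raise ValueError("invalid cohort accounting")
    return 100.0 * (cohort_size - nonrespondents) / cohort_size
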