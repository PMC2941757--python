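"""Weekly recovery and recurrence hazards for the depressive-episode model.

The course of a major depressive episode (MDE) is modelled in discrete
weekly time.  While depressed, an entity faces a weekly probability of
*recovery* driven by a complementary-log-log (discrete Weibull-like)
hazard whose linear predictor contains an intercept, age-group dummies
and the natural log of the weeks-depressed counter.  While recovered, it
faces a constant weekly probability of *recurrence* on the log-odds
scale, driven by age group, pain, smoking and childhood-stressor status
plus a fixed set of published cross-product (interaction) terms that let
the effect of each risk factor vary across age groups.

Entities are characterised by an :class:`AttributeProfile`: one of five
age groups crossed with three binary risk factors, giving the 40
distinct profiles the model distinguishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import expit

__all__ = [
    "AGE_GROUPS",
    "REFERENCE_AGE",
    "AttributeProfile",
    "RecoveryParameters",
    "RecurrenceParameters",
    "TimeConstants",
    "RECURRENCE_ROW_LABELS",
    "UnknownCoefficientError",
    "enumerate_profiles",
    "recovery_linear_predictor",
    "recovery_probability",
    "recurrence_linear_predictor",
    "recurrence_probability",
]

#: Ordered age groups; the first is the reference level (all dummies zero).
AGE_GROUPS: tuple[str, ...] = ("12-18", "19-25", "26-45", "46-65", "66+")
REFERENCE_AGE: str = AGE_GROUPS[0]

_AGE_LABEL = {
    "19-25": "Age 19-25",
    "26-45": "Age 26-45",
    "46-65": "Age 46-65",
    "66+": "Age 66 or more",
}


class UnknownCoefficientError(KeyError):
    """A coefficient was requested for a term the model does not define.

    The recurrence equation's term set is fixed and closed: rows absent
    from the published table (for example a plain pain-by-stressor
    product with no age factor) are structural zeros and are *not*
    addressable coefficients.
    """


@dataclass(frozen=True, order=True)
class AttributeProfile:
    """One of the 40 entity types: an age group plus three binary risk factors."""

    age_group: str
    pain: bool = False
    smoker: bool = False
    childhood_stressor: bool = False

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(
                f"age_group must be one of {AGE_GROUPS!r}, got {self.age_group!r}"
            )

    @property
    def age_index(self) -> int:
        return AGE_GROUPS.index(self.age_group)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        flags = "".join(
            c if on else "-"
            for c, on in zip("PSC", (self.pain, self.smoker, self.childhood_stressor))
        )
        return f"{self.age_group}/{flags}"


def enumerate_profiles() -> list[AttributeProfile]:
    """All 40 profiles in stable order: age-group major, then pain, smoker, stressor.

    The first element is the reference profile (age 12-18, no risk
    factors), which contributes only the intercepts to both hazards.
    """
    return [
        AttributeProfile(age, bool(p), bool(s), bool(c))
        for age in AGE_GROUPS
        for p in (0, 1)
        for s in (0, 1)
        for c in (0, 1)
    ]


# ---------------------------------------------------------------------------
# Recovery equation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryParameters:
    """Coefficients of the weekly recovery linear predictor.

    ``alpha`` is the intercept, the four ``age_*`` fields are dummy
    coefficients against the 12-18 reference group, and ``log_time``
    multiplies the natural log of the weeks-depressed counter.  The
    published calibrated ``log_time`` is negative, giving a recovery
    hazard that declines as an episode lengthens.
    """

    alpha: float
    age_19_25: float = 0.0
    age_26_45: float = 0.0
    age_46_65: float = 0.0
    age_66_plus: float = 0.0
    log_time: float = 0.0

    _AGE_FIELDS = ("age_19_25", "age_26_45", "age_46_65", "age_66_plus")

    def __post_init__(self) -> None:
        for name in ("alpha", *self._AGE_FIELDS, "log_time"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"recovery coefficient {name} must be finite, got {v}")

    def age_coefficient(self, profile: AttributeProfile) -> float:
        """Dummy-coded age contribution (0 for the reference group)."""
        idx = profile.age_index
        return 0.0 if idx == 0 else getattr(self, self._AGE_FIELDS[idx - 1])

    def as_dict(self) -> dict[str, float]:
        return {
            "alpha": self.alpha,
            "age_19_25": self.age_19_25,
            "age_26_45": self.age_26_45,
            "age_46_65": self.age_46_65,
            "age_66_plus": self.age_66_plus,
            "log_time": self.log_time,
        }


def recovery_linear_predictor(
    profile: AttributeProfile,
    weeks_depressed: int | np.ndarray,
    params: RecoveryParameters,
) -> float | np.ndarray:
    """Linear predictor of the weekly recovery hazard.

    ``weeks_depressed`` is the episode clock, evaluated at the end of
    each depressed week; it must be >= 1 (the hazard is first evaluated
    after one depressed week, where ln(1) = 0 leaves only the intercept
    and age terms).
    """
    weeks = np.asarray(weeks_depressed)
    if np.any(weeks < 1):
        raise ValueError("weeks_depressed must be >= 1 (episode clock starts at 1)")
    lp = params.alpha + params.age_coefficient(profile) + params.log_time * np.log(weeks)
    return float(lp) if np.isscalar(weeks_depressed) or weeks.ndim == 0 else lp


def recovery_probability(linear_predictor: float | np.ndarray) -> float | np.ndarray:
    """Inverse complementary-log-log link: ``1 - exp(-exp(lp))``.

    Maps the real line onto (0, 1) strictly monotonically.  NaN input is
    rejected; -inf is accepted as a "never recover" sentinel (probability
    exactly 0).
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if np.any(np.isnan(lp)):
        raise ValueError("recovery linear predictor is NaN")
    p = -np.expm1(-np.exp(lp))
    return float(p) if lp.ndim == 0 else p


# ---------------------------------------------------------------------------
# Recurrence equation
# ---------------------------------------------------------------------------

#: Published row labels of the recurrence equation, in table order:
#: intercept, 7 main effects, and the 23 printed cross-product terms.
#: Any label outside this list is a structural zero, not a coefficient.
RECURRENCE_ROW_LABELS: tuple[str, ...] = (
    "Intercept",
    "Age 19-25",
    "Age 26-45",
    "Age 46-65",
    "Age 66 or more",
    "Pain",
    "Smoking",
    "Childhood stressor",
    "Pain by age 26-45",
    "Pain by age 46-65",
    "Pain by age 66 or more",
    "Smoking by age 26-45",
    "Smoking by age 46-65",
    "Smoking by age 66 or more",
    "Childhood stressor by age 26-45",
    "Childhood stressor by age 46-65",
    "Childhood stressor by age 66 or more",
    "Pain by smoking",
    "Pain by smoking by age 19-25",
    "Pain by smoking by age 46-65",
    "Pain by smoking by age 66 or more",
    "Pain by childhood stressor by age 19-25",
    "Pain by childhood stressor by age 46-65",
    "Pain by childhood stressor by age 66 or more",
    "Smoking by childhood stressor by age 46-65",
    "Smoking by childhood stressor by age 66 or more",
    "Pain by smoking by childhood stressor",
    "Pain by smoking by childhood stressor by age 19-25",
    "Pain by smoking by childhood stressor by age 26-45",
    "Pain by smoking by childhood stressor by age 46-65",
    "Pain by smoking by childhood stressor by age 66 or more",
)


def _parse_row_label(label: str) -> tuple[bool, bool, bool, str | None]:
    """Decompose a row label into (pain, smoking, stressor, age-level) requirements."""
    pain = smoking = stressor = False
    age: str | None = None
    if label == "Intercept":
        return pain, smoking, stressor, age
    rest = label
    low = rest.lower()
    parts = low.split(" by ")
    for part in parts:
        part = part.strip()
        if part == "pain":
            pain = True
        elif part == "smoking":
            smoking = True
        elif part == "childhood stressor":
            stressor = True
        elif part.startswith("age "):
            token = part[4:].strip()
            if token in ("66 or more", "66+"):
                age = "66+"
            elif token in ("19-25", "26-45", "46-65"):
                age = token
            else:  # pragma: no cover - guarded by the closed label set
                raise ValueError(f"unrecognised age token in row label {label!r}")
        else:  # pragma: no cover
            raise ValueError(f"unrecognised factor {part!r} in row label {label!r}")
    return pain, smoking, stressor, age


#: label -> activation requirement, precomputed once.
_ROW_REQUIREMENTS: dict[str, tuple[bool, bool, bool, str | None]] = {
    label: _parse_row_label(label) for label in RECURRENCE_ROW_LABELS
}


@dataclass(frozen=True)
class RecurrenceParameters:
    """The closed coefficient set of the weekly recurrence log-odds equation.

    Holds exactly one real coefficient per published row label (31 in
    total).  A row contributes to a profile's linear predictor iff every
    factor named in its label is active in the profile; attribute
    combinations with no printed row are structural zeros.
    """

    coefficients: Mapping[str, float]

    def __post_init__(self) -> None:
        coeffs = dict(self.coefficients)
        missing = [k for k in RECURRENCE_ROW_LABELS if k not in coeffs]
        extra = [k for k in coeffs if k not in RECURRENCE_ROW_LABELS]
        if missing:
            raise ValueError(f"missing recurrence coefficients: {missing}")
        if extra:
            raise UnknownCoefficientError(
                f"unknown recurrence terms (structural zeros are not settable): {extra}"
            )
        for k, v in coeffs.items():
            if v in (math.inf,) or math.isnan(v):
                raise ValueError(f"recurrence coefficient {k!r} must be finite, got {v}")
        object.__setattr__(self, "coefficients", coeffs)

    @property
    def intercept(self) -> float:
        return self.coefficients["Intercept"]

    def coefficient(self, label: str) -> float:
        """Coefficient for a published row label; unknown labels raise."""
        try:
            return self.coefficients[label]
        except KeyError:
            raise UnknownCoefficientError(
                f"{label!r} is not a row of the recurrence equation "
                "(unprinted combinations are structural zeros)"
            ) from None

    def replace(self, **updates: float) -> "RecurrenceParameters":
        """Copy with some coefficients replaced (keyed by row label)."""
        coeffs = dict(self.coefficients)
        for k, v in updates.items():
            if k not in coeffs:
                raise UnknownCoefficientError(k)
            coeffs[k] = v
        return RecurrenceParameters(coeffs)

    def active_labels(self, profile: AttributeProfile) -> list[str]:
        """Row labels whose factor combination is fully active in *profile*."""
        out = []
        for label, (pain, smoking, stressor, age) in _ROW_REQUIREMENTS.items():
            if pain and not profile.pain:
                continue
            if smoking and not profile.smoker:
                continue
            if stressor and not profile.childhood_stressor:
                continue
            if age is not None and profile.age_group != age:
                continue
            out.append(label)
        return out


def recurrence_linear_predictor(
    profile: AttributeProfile, params: RecurrenceParameters
) -> float:
    """Weekly recurrence log-odds for a profile (time-constant).

    Sum of the intercept and every main-effect and interaction
    coefficient whose defining attribute combination is fully active in
    the profile.
    """
    return sum(params.coefficients[label] for label in params.active_labels(profile))


def recurrence_probability(linear_predictor: float | np.ndarray) -> float | np.ndarray:
    """Inverse logit: odds = exp(lp), probability = odds / (1 + odds).

    NaN is rejected; -inf is accepted as a "never recur" sentinel
    (probability exactly 0).
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if np.any(np.isnan(lp)):
        raise ValueError("recurrence linear predictor is NaN")
    p = expit(lp)
    return float(p) if lp.ndim == 0 else p


# ---------------------------------------------------------------------------
# Time constants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeConstants:
    """Clock layout of the simulation.

    Weeks are indexed 1..``horizon_weeks``.  Onsets fall uniformly in
    weeks 1..``onset_window_weeks``; the baseline interview occurs at
    the end of the onset window and the follow-up interview at the
    horizon, two years (104 weeks) later.  Each interview asks about the
    ``past_year_window_weeks`` weeks up to and including the interview
    week.
    """

    horizon_weeks: int = 208
    onset_window_weeks: int = 104
    interview_weeks: tuple[int, ...] = (104, 208)
    past_year_window_weeks: int = 52

    def __post_init__(self) -> None:
        if self.horizon_weeks < 1 or self.onset_window_weeks < 1:
            raise ValueError("horizon and onset window must be positive")
        if self.past_year_window_weeks < 1:
            raise ValueError("past-year window must be positive")
        if self.interview_weeks:
            if self.interview_weeks[0] != self.onset_window_weeks:
                raise ValueError("onset window must end at the baseline interview")
            if self.interview_weeks[-1] != self.horizon_weeks:
                raise ValueError("horizon must equal the last interview week")
            if list(self.interview_weeks) != sorted(self.interview_weeks):
                raise ValueError("interview weeks must be increasing")

    @property
    def baseline_week(self) -> int:
        return self.interview_weeks[0]

    @property
    def followup_week(self) -> int:
        return self.interview_weeks[-1]
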