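"""Calibration of the hazard equations against survey-side targets.

The weekly hazard coefficients are not directly estimable from the
survey, so they are recovered by simulation: pick coefficients, run the
cohort, push it through the observation layer, and compare the
per-profile consecutive-positivity proportions and per-age-group
weeks-category distributions with target fitted values from the survey
regression models.  The objective is the equally weighted sum of
squared residuals over both blocks; a bounded derivative-free search
(Nelder-Mead simplex with seeded random restarts) minimises it over a
user-selected subset of coefficients with the rest pinned.

Common random numbers make the objective a deterministic function of
the parameters for a fixed simulation seed, so the search is
well-posed.  With positivity targets alone, recovery and recurrence
parameters trade off (a long persistent episode and a recover-then-
recur path produce the same consecutive positivity); adding the
weeks-category block is what pins the recovery side down.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .hazards import (
    AGE_GROUPS,
    RecoveryParameters,
    RecurrenceParameters,
    enumerate_profiles,
)
from .observe import (
    WEEKS_CATEGORIES,
    category_distribution_by_age,
    observe_cohort,
    summarize_by_profile,
)
from .regression import BinaryModelFit, OrdinalModelFit, fitted_profile_probabilities
from .simulate import SimulationConfig, simulate_cohort

__all__ = [
    "CalibrationTargets",
    "CalibrationResult",
    "targets_from_models",
    "simulated_summaries",
    "targets_from_simulation",
    "objective_value",
    "calibrate",
]

_RECOVERY_FIELDS = ("alpha", "age_19_25", "age_26_45", "age_46_65", "age_66_plus", "log_time")


@dataclass(frozen=True)
class CalibrationTargets:
    """Target fitted values the simulation should reproduce.

    ``positivity`` holds one consecutive-positivity probability per
    profile (40 values in standard profile order); ``category_by_age``
    holds one 4-category weeks distribution per age group (rows sum
    to 1).  Either block may be ``None`` for a partial objective.
    """

    positivity: np.ndarray | None
    category_by_age: pd.DataFrame | None

    def __post_init__(self) -> None:
        if self.positivity is not None:
            pos = np.asarray(self.positivity, dtype=float)
            if pos.shape != (40,):
                raise ValueError("positivity targets must have one entry per profile (40)")
            if np.nanmin(pos) < 0 or np.nanmax(pos) > 1:
                raise ValueError("positivity targets must be probabilities")
            object.__setattr__(self, "positivity", pos)
        if self.category_by_age is not None:
            cba = self.category_by_age
            if list(cba.columns) != list(WEEKS_CATEGORIES) or list(cba.index) != list(AGE_GROUPS):
                raise ValueError("category targets must be age-group x weeks-category")
            sums = cba.sum(axis=1).to_numpy()
            if not np.allclose(sums[~np.isnan(sums)], 1.0, atol=1e-6):
                raise ValueError("category target rows must sum to 1")
        if self.positivity is None and self.category_by_age is None:
            raise ValueError("at least one target block is required")

    def drop_positivity(self) -> "CalibrationTargets":
        return CalibrationTargets(None, self.category_by_age)

    def drop_categories(self) -> "CalibrationTargets":
        return CalibrationTargets(self.positivity, None)


def targets_from_models(binary: BinaryModelFit, ordinal: OrdinalModelFit) -> CalibrationTargets:
    """Wrap per-profile fitted probabilities from the survey models as targets."""
    profiles = enumerate_profiles()
    fitted = fitted_profile_probabilities(binary, ordinal, profiles)
    positivity = fitted["p_followup_positive"].to_numpy()
    # Age-only ordinal model: take the (identical) distribution of the
    # first profile in each age group.
    rows = {}
    for age in AGE_GROUPS:
        sub = fitted[fitted["age_group"] == age].iloc[0]
        rows[age] = {c: float(sub[f"p_weeks_{c}"]) for c in WEEKS_CATEGORIES}
    return CalibrationTargets(positivity, pd.DataFrame.from_dict(rows, orient="index"))


def simulated_summaries(
    recovery: RecoveryParameters,
    recurrence: RecurrenceParameters,
    sim_config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate, observe and summarise one cohort at the given parameters.

    Returns the 40-row per-profile summary and the 5x4 per-age-group
    category distribution, using the config's seed (common random
    numbers across parameter settings).
    """
    config = replace(sim_config, recovery=recovery, recurrence=recurrence)
    cohort = simulate_cohort(config)
    obs = observe_cohort(cohort, config.time)
    return summarize_by_profile(obs), category_distribution_by_age(obs)


def targets_from_simulation(
    recovery: RecoveryParameters,
    recurrence: RecurrenceParameters,
    sim_config: SimulationConfig,
) -> CalibrationTargets:
    """Self-generated targets: summaries of a simulation at known parameters."""
    summary, cat = simulated_summaries(recovery, recurrence, sim_config)
    return CalibrationTargets(summary["p_followup_positive"].to_numpy(), cat)


def objective_value(
    recovery: RecoveryParameters,
    recurrence: RecurrenceParameters,
    targets: CalibrationTargets,
    sim_config: SimulationConfig,
) -> float:
    """Sum of squared residuals between simulated summaries and targets.

    Profiles (or age groups) with no included simulated record are
    excluded with a warning; the two residual blocks are equally
    weighted.
    """
    summary, cat = simulated_summaries(recovery, recurrence, sim_config)
    total = 0.0
    if targets.positivity is not None:
        sim_pos = summary["p_followup_positive"].to_numpy()
        valid = ~np.isnan(sim_pos) & ~np.isnan(targets.positivity)
        if not valid.all():
            warnings.warn(
                f"{(~valid).sum()} empty profile cells excluded from the positivity block",
                stacklevel=2,
            )
        total += float(np.sum((sim_pos[valid] - targets.positivity[valid]) ** 2))
    if targets.category_by_age is not None:
        sim_c = cat.to_numpy()
        tgt_c = targets.category_by_age.to_numpy()
        valid = ~np.isnan(sim_c) & ~np.isnan(tgt_c)
        if not valid.all():
            warnings.warn("empty age-group cells excluded from the category block", stacklevel=2)
        total += float(np.sum((sim_c[valid] - tgt_c[valid]) ** 2))
    return total


@dataclass
class CalibrationResult:
    """Outcome of a calibration run."""

    recovery: RecoveryParameters
    recurrence: RecurrenceParameters
    objective: float
    n_evaluations: int
    trace: pd.DataFrame  # one row per objective evaluation
    seed: int
    budget_exhausted: bool
    free_coefficients: tuple[str, ...]
    #: best point of each restart: {"x": {name: value}, "objective": float}
    restart_results: list[dict] = field(default_factory=list)


def _apply_free(
    base_recovery: RecoveryParameters,
    base_recurrence: RecurrenceParameters,
    names: Sequence[str],
    values: np.ndarray,
) -> tuple[RecoveryParameters, RecurrenceParameters]:
    rec_updates: dict[str, float] = {}
    recur_updates: dict[str, float] = {}
    for name, v in zip(names, values):
        scope, _, key = name.partition(".")
        if scope == "recovery":
            if key not in _RECOVERY_FIELDS:
                raise ValueError(f"unknown recovery coefficient {key!r}")
            rec_updates[key] = float(v)
        elif scope == "recurrence":
            recur_updates[key] = float(v)
        else:
            raise ValueError(
                f"free coefficient {name!r} must be 'recovery.<field>' or 'recurrence.<row label>'"
            )
    recovery = dataclasses.replace(base_recovery, **rec_updates) if rec_updates else base_recovery
    recurrence = base_recurrence.replace(**recur_updates) if recur_updates else base_recurrence
    return recovery, recurrence


def calibrate(
    targets: CalibrationTargets,
    sim_config: SimulationConfig,
    search_spec: Mapping[str, tuple[float, float]],
    budget: int = 300,
    restarts: int = 2,
    seed: int = 0,
    random_starts_only: bool = False,
) -> CalibrationResult:
    """Bounded derivative-free minimisation of the calibration objective.

    ``search_spec`` maps free-coefficient names (``recovery.alpha``,
    ``recurrence.Intercept``, ...) to box bounds; all other
    coefficients stay pinned at the values in ``sim_config``.  Each
    restart runs a bounded Nelder-Mead simplex from a seeded start
    point (box centre first, then uniform draws in the box;
    ``random_starts_only`` makes every start a uniform draw, useful for
    probing identifiability via the spread of ``restart_results``); the
    total evaluation budget is split across restarts.  Deterministic for a
    fixed seed: the simulation seed inside the objective is unchanged
    across evaluations (common random numbers) and restart points come
    from a generator seeded here.

    With an empty ``search_spec`` the objective is evaluated once at
    the pinned values.
    """
    names = tuple(search_spec)
    bounds = [tuple(map(float, search_spec[n])) for n in names]
    for n, (lo, hi) in zip(names, bounds):
        if not lo < hi:
            raise ValueError(f"bounds for {n!r} must satisfy lo < hi")
    base_recovery, base_recurrence = sim_config.recovery, sim_config.recurrence

    trace_rows: list[dict] = []

    def evaluate(x: np.ndarray) -> float:
        recovery, recurrence = _apply_free(base_recovery, base_recurrence, names, x)
        val = objective_value(recovery, recurrence, targets, sim_config)
        trace_rows.append(
            {"evaluation": len(trace_rows) + 1, **dict(zip(names, map(float, x))), "objective": val}
        )
        return val

    if not names:
        val = evaluate(np.empty(0))
        return CalibrationResult(
            recovery=base_recovery,
            recurrence=base_recurrence,
            objective=val,
            n_evaluations=1,
            trace=pd.DataFrame(trace_rows),
            seed=seed,
            budget_exhausted=False,
            free_coefficients=names,
        )

    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = [] if random_starts_only else [0.5 * (lo + hi)]
    while len(starts) < restarts:
        starts.append(lo + rng.random(len(names)) * (hi - lo))

    per_restart = max(budget // max(restarts, 1), 2 * len(names) + 2)
    best_x, best_val = None, np.inf
    exhausted = False
    restart_results: list[dict] = []
    for x0 in starts:
        remaining = budget - len(trace_rows)
        if remaining < len(names) + 1:
            exhausted = True
            break
        res = optimize.minimize(
            evaluate,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={
                "maxfev": min(per_restart, remaining),
                "xatol": 1e-3,
                "fatol": 1e-10,
                "adaptive": len(names) > 2,
            },
        )
        if not res.success and "maximum number of function evaluations" in str(res.message).lower():
            exhausted = True
        restart_results.append(
            {"x": dict(zip(names, map(float, res.x))), "objective": float(res.fun)}
        )
        if res.fun < best_val:
            best_val, best_x = float(res.fun), np.asarray(res.x)

    recovery, recurrence = _apply_free(base_recovery, base_recurrence, names, best_x)
    return CalibrationResult(
        recovery=recovery,
        recurrence=recurrence,
        objective=best_val,
        n_evaluations=len(trace_rows),
        trace=pd.DataFrame(trace_rows),
        seed=seed,
        budget_exhausted=exhausted,
        free_coefficients=names,
        restart_results=restart_results,
    )
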