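"""End-to-end pipeline: simulate -> observe -> summarize -> fit -> calibrate.

A run is fully described by a config mapping (YAML on disk) plus a
seed, and writes plain CSV/JSON artifacts to an output directory:
cohort and observation tables, the 40-row per-profile summary, survey
model fits, an optional calibration result with its evaluation trace,
and two plot-ready data tables (cumulative recovery by age group and
fitted-versus-simulated positivity).  Rerunning with the same config
and seed reproduces every artifact byte for byte.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibrate import calibrate, targets_from_models
from .hazards import AGE_GROUPS, AttributeProfile, TimeConstants
from .observe import observations_to_frame, observe_cohort, summarize_by_profile
from .params_io import (
    published_recovery,
    published_recurrence,
    read_recovery_params,
    read_recurrence_params,
)
from .regression import fit_binary_logistic, fit_ordinal_logistic
from .simulate import SimulationConfig, simulate_cohort, simulate_durations
from .synth import PopulationSpec, generate_survey

__all__ = ["load_run_config", "build_sim_config", "run_pipeline", "PipelineError"]

_DEFAULT_CONFIG: dict[str, Any] = {
    "n_entities_per_profile": 100,
    "reset_clock_on_recurrence": False,
    "recovery_params": None,  # path; defaults to the packaged published values
    "recurrence_params": None,
    "survey": {"n_respondents": 1857},
    "recovery_curve_entities": 2000,
    "calibration": {
        "enabled": False,
        "free": {},  # name -> [lo, hi]
        "budget": 200,
        "restarts": 2,
    },
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_run_config(path: str | Path | None) -> dict[str, Any]:
    """Run config from YAML merged over defaults (``None`` -> pure defaults)."""
    if path is None:
        return dict(_DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise PipelineError(f"config: expected a mapping at top level of {path}")
    return _merge(_DEFAULT_CONFIG, user)


def build_sim_config(config: Mapping[str, Any], seed: int) -> SimulationConfig:
    recovery = (
        read_recovery_params(config["recovery_params"])
        if config.get("recovery_params")
        else published_recovery()
    )
    recurrence = (
        read_recurrence_params(config["recurrence_params"])
        if config.get("recurrence_params")
        else published_recurrence()
    )
    return SimulationConfig(
        recovery=recovery,
        recurrence=recurrence,
        n_entities_per_profile=int(config["n_entities_per_profile"]),
        time=TimeConstants(),
        seed=seed,
        reset_clock_on_recurrence=bool(config["reset_clock_on_recurrence"]),
    )


def cohort_frame(records, time: TimeConstants) -> pd.DataFrame:
    """Flat per-entity table: profile, onset, episode count, window week counts."""
    w = time.past_year_window_weeks
    rows = []
    for r in records:
        rows.append(
            {
                "age_group": r.profile.age_group,
                "pain": int(r.profile.pain),
                "smoker": int(r.profile.smoker),
                "childhood_stressor": int(r.profile.childhood_stressor),
                "onset_week": r.onset_week,
                "n_episodes": len(r.episodes),
                "cumulative_weeks_depressed": r.cumulative_weeks_depressed,
                "weeks_baseline_window": int(
                    r.depressed[time.baseline_week - w : time.baseline_week].sum()
                ),
                "weeks_followup_window": int(
                    r.depressed[time.followup_week - w : time.followup_week].sum()
                ),
            }
        )
    return pd.DataFrame(rows)


def recovery_curve_by_age(
    sim_config: SimulationConfig, n_per_group: int, max_weeks: int = 104
) -> pd.DataFrame:
    """Cumulative probability of recovery by episode week, per age group.

    Simulated from the recovery hazard alone (single episode starting
    at week 1), the quantity behind the published cumulative-recovery
    figure.
    """
    rows = []
    for i, age in enumerate(AGE_GROUPS):
        profile = AttributeProfile(age)
        dur, event = simulate_durations(
            profile,
            n_per_group,
            sim_config.recovery,
            max_weeks=max_weeks,
            rng=np.random.default_rng([sim_config.seed, 1000 + i]),
        )
        for week in range(1, max_weeks + 1):
            rows.append(
                {
                    "age_group": age,
                    "week": week,
                    "cumulative_recovered": float(np.mean(event & (dur <= week))),
                }
            )
    return pd.DataFrame(rows)


def _binary_fit_dict(fit) -> dict:
    return {
        "terms": list(fit.terms),
        "intercept": fit.intercept,
        "coefficients": fit.coefficients,
        "standard_errors": fit.standard_errors,
        "odds_ratios": fit.odds_ratios,
        "conf_int": {k: list(v) for k, v in fit.conf_int.items()},
        "converged": fit.converged,
    }


def _ordinal_fit_dict(fit) -> dict:
    return {
        "terms": list(fit.terms),
        "coefficients": fit.coefficients,
        "cut_points": list(fit.cut_points),
        "standard_errors": fit.standard_errors,
        "converged": fit.converged,
    }


def run_pipeline(config: Mapping[str, Any], seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Execute all stages and write artifacts; returns the artifact paths.

    Stage failures raise :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def _stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - diagnostics must name the stage
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    sim_config = _stage("configure", lambda: build_sim_config(config, seed))

    cohort = _stage("simulate", lambda: simulate_cohort(sim_config))
    cohort_df = cohort_frame(cohort, sim_config.time)
    artifacts["cohort"] = out / "cohort.csv"
    cohort_df.to_csv(artifacts["cohort"], index=False)

    obs = _stage("observe", lambda: observe_cohort(cohort, sim_config.time))
    artifacts["observations"] = out / "observations.csv"
    observations_to_frame(obs).to_csv(artifacts["observations"], index=False)

    summary = _stage("summarize", lambda: summarize_by_profile(obs))
    artifacts["summary"] = out / "summary.csv"
    summary.to_csv(artifacts["summary"], index=False)

    def _fit():
        spec_kwargs = dict(config.get("survey", {}))
        spec = PopulationSpec(**{**spec_kwargs, "seed": seed})
        survey = generate_survey(spec)
        return fit_binary_logistic(survey), fit_ordinal_logistic(survey)

    binary_fit, ordinal_fit = _stage("fit", _fit)
    artifacts["model_fits"] = out / "model_fits.json"
    artifacts["model_fits"].write_text(
        json.dumps(
            {"binary": _binary_fit_dict(binary_fit), "ordinal": _ordinal_fit_dict(ordinal_fit)},
            indent=2,
        )
    )

    targets = _stage("targets", lambda: targets_from_models(binary_fit, ordinal_fit))

    # Plot data tables.
    curve = _stage(
        "recovery_curve",
        lambda: recovery_curve_by_age(sim_config, int(config["recovery_curve_entities"])),
    )
    artifacts["recovery_curve"] = out / "recovery_curve_by_age.csv"
    curve.to_csv(artifacts["recovery_curve"], index=False)

    scatter = summary[["age_group", "pain", "smoker", "childhood_stressor"]].copy()
    scatter["fitted_positivity"] = targets.positivity
    scatter["simulated_positivity"] = summary["p_followup_positive"].to_numpy()
    artifacts["fitted_vs_simulated"] = out / "fitted_vs_simulated.csv"
    scatter.to_csv(artifacts["fitted_vs_simulated"], index=False)

    cal_cfg = config.get("calibration", {})
    if cal_cfg.get("enabled"):
        search_spec = {k: tuple(v) for k, v in cal_cfg.get("free", {}).items()}

        def _calibrate():
            return calibrate(
                targets,
                sim_config,
                search_spec,
                budget=int(cal_cfg.get("budget", 200)),
                restarts=int(cal_cfg.get("restarts", 2)),
                seed=seed,
            )

        result = _stage("calibrate", _calibrate)
        artifacts["calibration"] = out / "calibration.json"
        artifacts["calibration"].write_text(
            json.dumps(
                {
                    "recovery": result.recovery.as_dict(),
                    "recurrence": dict(result.recurrence.coefficients),
                    "objective": result.objective,
                    "n_evaluations": result.n_evaluations,
                    "seed": result.seed,
                    "budget_exhausted": result.budget_exhausted,
                    "free_coefficients": list(result.free_coefficients),
                },
                indent=2,
            )
        )
        artifacts["calibration_trace"] = out / "calibration_trace.csv"
        result.trace.to_csv(artifacts["calibration_trace"], index=False)

    artifacts["run_log"] = out / "run_log.json"
    artifacts["run_log"].write_text(
        json.dumps(
            {
                "seed": seed,
                "config": {k: v for k, v in config.items()},
                "mdesim_version": __version__,
                "python_version": platform.python_version(),
            },
            indent=2,
            default=str,
        )
    )
    return artifacts
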