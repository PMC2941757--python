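"""Synthetic biennial-survey respondent generator with known ground truth.

The real survey microdata are restricted-access, so every downstream
stage (regression fits, calibration targets) is exercised on synthetic
respondent tables drawn from known parameters: independent covariate
draws at configurable prevalences, a consecutive-positivity outcome
from a binary logistic model, and a four-category weeks-depressed
outcome from a proportional-odds model.  Fitting the matching model to
a generated table recovers the generating truth (bias shrinking with
n), which is the backbone of the test suite.

The default covariate prevalences and the ordinal cut-points are
fabricated (the survey does not publish them); the default effect
sizes are the published odds ratios and ordinal coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .hazards import AGE_GROUPS
from .observe import WEEKS_CATEGORIES
from .regression import design_matrix

__all__ = ["PopulationSpec", "generate_covariates", "generate_consecutive_outcome",
           "generate_weeks_category_outcome", "generate_survey"]

#: Published effect sizes usable as generating truth.
PUBLISHED_BINARY_LOG_ORS = {
    "age_26_45": float(np.log(1.5)),
    "smoker": float(np.log(1.5)),
    "childhood_stressor": float(np.log(2.0)),
    "pain": float(np.log(1.6)),
}
PUBLISHED_ORDINAL_COEFFS = {
    "age_19_25": -0.058,
    "age_26_45": 0.166,
    "age_46_65": 0.441,
    "age_66_plus": 0.486,
}


@dataclass(frozen=True)
class PopulationSpec:
    """Ground-truth parameters of a synthetic respondent population.

    Sample-size default matches the published consecutive-positivity
    analysis file (1,857 respondents); tests needing precision use
    larger n explicitly.
    """

    n_respondents: int = 1857
    age_probabilities: tuple[float, ...] = (0.15, 0.15, 0.35, 0.25, 0.10)
    p_pain: float = 0.10
    p_smoker: float = 0.30
    p_childhood_stressor: float = 0.30
    binary_intercept: float = -2.0
    binary_log_odds_ratios: dict[str, float] = field(
        default_factory=lambda: dict(PUBLISHED_BINARY_LOG_ORS)
    )
    ordinal_cut_points: tuple[float, float, float] = (0.0, 0.8, 1.6)
    ordinal_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(PUBLISHED_ORDINAL_COEFFS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.age_probabilities)
        if len(probs) != len(AGE_GROUPS) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("age_probabilities must be a 5-vector summing to 1")
        for p in (self.p_pain, self.p_smoker, self.p_childhood_stressor):
            if not 0.0 <= p <= 1.0:
                raise ValueError("prevalences must lie in [0, 1]")
        if list(self.ordinal_cut_points) != sorted(self.ordinal_cut_points):
            raise ValueError("ordinal cut points must be increasing")


def generate_covariates(spec: PopulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Independent covariate draws from the spec's marginal distributions."""
    n = spec.n_respondents
    age = rng.choice(len(AGE_GROUPS), size=n, p=spec.age_probabilities)
    return pd.DataFrame(
        {
            "age_group": [AGE_GROUPS[i] for i in age],
            "pain": (rng.random(n) < spec.p_pain).astype(int),
            "smoker": (rng.random(n) < spec.p_smoker).astype(int),
            "childhood_stressor": (rng.random(n) < spec.p_childhood_stressor).astype(int),
        }
    )


def _linear_predictor(covariates: pd.DataFrame, coeffs: dict[str, float]) -> np.ndarray:
    terms = tuple(coeffs)
    X = design_matrix(covariates, terms).to_numpy()
    beta = np.array([coeffs[t] for t in terms])
    return X @ beta


def generate_consecutive_outcome(
    covariates: pd.DataFrame,
    intercept: float,
    log_odds_ratios: dict[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli consecutive-positivity outcomes from a logistic model."""
    p = expit(intercept + _linear_predictor(covariates, log_odds_ratios))
    return (rng.random(len(covariates)) < p).astype(int)


def category_probabilities(
    covariates: pd.DataFrame,
    cut_points: tuple[float, float, float],
    coefficients: dict[str, float],
) -> np.ndarray:
    """Closed-form proportional-odds category probabilities, row per respondent.

    Convention: ``P(Y <= j | x) = expit(cut_j - x @ beta)``.
    """
    xb = _linear_predictor(covariates, coefficients)
    cdf = expit(np.asarray(cut_points)[None, :] - xb[:, None])
    cdf = np.hstack([cdf, np.ones((len(xb), 1))])
    return np.diff(cdf, prepend=0.0, axis=1)


def generate_weeks_category_outcome(
    covariates: pd.DataFrame,
    cut_points: tuple[float, float, float],
    coefficients: dict[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Ordered weeks-category draws from the proportional-odds distribution."""
    probs = category_probabilities(covariates, cut_points, coefficients)
    u = rng.random(len(covariates))
    idx = (u[:, None] >= np.cumsum(probs, axis=1)).sum(axis=1)
    return np.array(WEEKS_CATEGORIES, dtype=object)[idx]


def generate_survey(spec: PopulationSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Full synthetic respondent table with both outcomes.

    Columns: the four covariates plus ``followup_positive`` and
    ``weeks_category``.  Deterministic given ``spec.seed`` when no
    generator is supplied.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    cov = generate_covariates(spec, rng)
    cov["followup_positive"] = generate_consecutive_outcome(
        cov, spec.binary_intercept, spec.binary_log_odds_ratios, rng
    )
    cov["weeks_category"] = generate_weeks_category_outcome(
        cov, spec.ordinal_cut_points, spec.ordinal_coefficients, rng
    )
    return cov
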