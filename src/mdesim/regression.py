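"""Survey-side regression models and diagnostics.

Two models summarise what the biennial survey can estimate directly and
serve as calibration anchors for the simulation: a binary logistic
model for being past-year positive at two consecutive interviews, and a
proportional-odds (ordinal logistic) model for the four-category
weeks-depressed-in-past-year outcome.  Brant's test checks the
proportional-odds assumption by fitting the separate cumulative binary
logits and testing equality of each covariate's coefficients across
them with a Wald statistic.

Maximum-likelihood fitting is delegated to statsmodels (Logit,
OrderedModel, GLM); Brant's test and the per-profile prediction
machinery are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .hazards import AttributeProfile
from .observe import WEEKS_CATEGORIES

__all__ = [
    "TERM_COLUMNS",
    "SeparationError",
    "BinaryModelFit",
    "OrdinalModelFit",
    "BrantResult",
    "BrantUntestableError",
    "fit_binary_logistic",
    "fit_ordinal_logistic",
    "fit_discrete_time_cloglog",
    "brant_test",
    "fitted_profile_probabilities",
]

#: Supported design terms and how to evaluate them on a respondent table.
TERM_COLUMNS = (
    "age_19_25",
    "age_26_45",
    "age_46_65",
    "age_66_plus",
    "pain",
    "smoker",
    "childhood_stressor",
)

_AGE_TERM_TO_GROUP = {
    "age_19_25": "19-25",
    "age_26_45": "26-45",
    "age_46_65": "46-65",
    "age_66_plus": "66+",
}

#: Term lists of the two published survey models.
BINARY_MODEL_TERMS = ("age_26_45", "smoker", "childhood_stressor", "pain")
ORDINAL_MODEL_TERMS = ("age_19_25", "age_26_45", "age_46_65", "age_66_plus")


class SeparationError(RuntimeError):
    """The likelihood is unbounded (perfect or quasi-perfect separation)."""


class BrantUntestableError(RuntimeError):
    """A cumulative split has no events, so its binary logit cannot be fit."""


def design_matrix(records: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Dummy-coded design columns for *terms* evaluated on a respondent table."""
    cols = {}
    for t in terms:
        if t in _AGE_TERM_TO_GROUP:
            cols[t] = (records["age_group"] == _AGE_TERM_TO_GROUP[t]).astype(float)
        elif t in ("pain", "smoker", "childhood_stressor"):
            cols[t] = records[t].astype(float)
        else:
            raise ValueError(f"unknown design term {t!r}")
    return pd.DataFrame(cols, index=records.index)


def profile_design(profile: AttributeProfile, terms: Sequence[str]) -> np.ndarray:
    vals = []
    for t in terms:
        if t in _AGE_TERM_TO_GROUP:
            vals.append(float(profile.age_group == _AGE_TERM_TO_GROUP[t]))
        elif t == "pain":
            vals.append(float(profile.pain))
        elif t == "smoker":
            vals.append(float(profile.smoker))
        elif t == "childhood_stressor":
            vals.append(float(profile.childhood_stressor))
        else:
            raise ValueError(f"unknown design term {t!r}")
    return np.array(vals)


@dataclass
class BinaryModelFit:
    """Binary logistic fit: consecutive past-year positivity."""

    terms: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    odds_ratios: dict[str, float]
    conf_int: dict[str, tuple[float, float]]  # Wald 95% CI on the OR scale
    converged: bool

    def predict_probability(self, profile: AttributeProfile) -> float:
        x = profile_design(profile, self.terms)
        beta = np.array([self.coefficients[t] for t in self.terms])
        return float(expit(self.intercept + x @ beta))


@dataclass
class OrdinalModelFit:
    """Proportional-odds fit for the four weeks-depressed categories.

    Convention: ``P(Y <= j | x) = expit(cut_j - x @ beta)``, so positive
    coefficients shift mass toward longer-duration categories.
    """

    terms: tuple[str, ...]
    coefficients: dict[str, float]
    cut_points: tuple[float, ...]
    standard_errors: dict[str, float]
    converged: bool

    def __post_init__(self) -> None:
        if list(self.cut_points) != sorted(self.cut_points):
            raise ValueError("cut points must be strictly increasing")

    def predict_category_distribution(self, profile: AttributeProfile) -> np.ndarray:
        x = profile_design(profile, self.terms)
        beta = np.array([self.coefficients[t] for t in self.terms])
        xb = float(x @ beta)
        cdf = np.concatenate((expit(np.array(self.cut_points) - xb), [1.0]))
        return np.diff(cdf, prepend=0.0)


def _fit_logit(y: np.ndarray, X):
    """Logit MLE with statsmodels' separation warning promoted to an error."""
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("error", PerfectSeparationWarning)
        _warnings.simplefilter("ignore", RuntimeWarning)
        try:
            return sm.Logit(y, X).fit(disp=0, maxiter=200)
        except PerfectSeparationWarning as exc:
            raise PerfectSeparationError(str(exc)) from exc


def _check_converged_params(params: np.ndarray, converged: bool) -> None:
    if not converged or not np.all(np.isfinite(params)):
        raise SeparationError("logistic fit failed to converge")
    if np.max(np.abs(params)) > 30:
        raise SeparationError(
            "coefficient estimates diverged; the data are (quasi-)separated"
        )


def fit_binary_logistic(
    records: pd.DataFrame,
    terms: Sequence[str] = BINARY_MODEL_TERMS,
    outcome: str = "followup_positive",
) -> BinaryModelFit:
    """Maximum-likelihood binary logistic regression with Wald intervals.

    Separation and non-convergence raise :class:`SeparationError`
    explicitly rather than returning garbage estimates.
    """
    y = records[outcome].astype(float).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("outcome needs at least one event and one non-event")
    X = sm.add_constant(design_matrix(records, terms), has_constant="add")
    try:
        res = _fit_logit(y, X)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(str(exc)) from exc
    _check_converged_params(res.params.to_numpy(), bool(res.mle_retvals["converged"]))
    params = res.params
    bse = res.bse
    z = stats.norm.ppf(0.975)
    terms = tuple(terms)
    return BinaryModelFit(
        terms=terms,
        intercept=float(params["const"]),
        coefficients={t: float(params[t]) for t in terms},
        standard_errors={t: float(bse[t]) for t in terms},
        odds_ratios={t: float(np.exp(params[t])) for t in terms},
        conf_int={
            t: (
                float(np.exp(params[t] - z * bse[t])),
                float(np.exp(params[t] + z * bse[t])),
            )
            for t in terms
        },
        converged=True,
    )


def fit_ordinal_logistic(
    records: pd.DataFrame,
    terms: Sequence[str] = ORDINAL_MODEL_TERMS,
    outcome: str = "weeks_category",
) -> OrdinalModelFit:
    """Proportional-odds MLE for the ordered weeks-depressed categories."""
    cats = [c for c in WEEKS_CATEGORIES if (records[outcome] == c).any()]
    if len(cats) < 2:
        raise ValueError("need at least two observed outcome categories")
    endog = pd.Series(
        pd.Categorical(records[outcome], categories=cats, ordered=True), name=outcome
    )
    X = design_matrix(records, terms)
    model = OrderedModel(endog, X, distr="logit")
    res = model.fit(method="bfgs", disp=0, maxiter=500)
    params = res.params.to_numpy()
    if not res.mle_retvals.get("converged", True) or not np.all(np.isfinite(params)):
        raise SeparationError("ordinal logistic fit failed to converge")
    k = len(terms)
    # OrderedModel parameterizes P(Y <= j) = F(threshold_j - x @ beta).
    cuts = model.transform_threshold_params(params)[1:-1]
    return OrdinalModelFit(
        terms=tuple(terms),
        coefficients={t: float(params[i]) for i, t in enumerate(terms)},
        cut_points=tuple(float(c) for c in cuts),
        standard_errors={t: float(res.bse.iloc[i]) for i, t in enumerate(terms)},
        converged=True,
    )


def fit_discrete_time_cloglog(
    durations: np.ndarray,
    events: np.ndarray,
    covariates: pd.DataFrame,
    include_log_week: bool = True,
):
    """Discrete-time survival fit on person-week data with a cloglog link.

    Expands each subject's duration into one row per at-risk week
    (event indicator 1 only in the final week of an uncensored spell)
    and fits a binomial GLM with complementary-log-log link on
    ``ln(week)`` plus the supplied subject-level covariates.  Returns
    the statsmodels results object; with data generated by the weekly
    recovery hazard, the fitted coefficients estimate that hazard's
    linear-predictor coefficients directly.
    """
    durations = np.asarray(durations, dtype=np.int64)
    events = np.asarray(events, dtype=bool)
    n = durations.size
    idx = np.repeat(np.arange(n), durations)
    week = np.concatenate([np.arange(1, d + 1) for d in durations])
    y = np.zeros(idx.size)
    last = np.cumsum(durations) - 1
    y[last[events]] = 1.0
    X = pd.DataFrame({"const": np.ones(idx.size)})
    if include_log_week:
        X["log_week"] = np.log(week)
    for col in covariates.columns:
        X[col] = covariates[col].to_numpy()[idx]
    model = sm.GLM(y, X, family=sm.families.Binomial(link=sm.families.links.CLogLog()))
    return model.fit()


@dataclass
class BrantResult:
    """Wald test of coefficient equality across the cumulative binary logits."""

    chi_square: float
    df: int
    p_value: float
    per_variable: pd.DataFrame  # chi2, df, p per covariate


def brant_test(
    records: pd.DataFrame,
    terms: Sequence[str] = ORDINAL_MODEL_TERMS,
    outcome: str = "weeks_category",
    categories: Sequence[str] = WEEKS_CATEGORIES,
) -> BrantResult:
    """Brant's proportional-odds test.

    Fits the J-1 cumulative binary logits P(Y > category_j) separately,
    assembles the joint covariance of their slope estimates (using the
    fitted-probability cross-products of the separate fits), and tests
    equality of each covariate's coefficients across the J-1 equations.
    Omnibus degrees of freedom: (J-2) * K for K covariates.  The
    statistic is invariant to covariate relabeling.
    """
    cats = list(categories)
    J = len(cats)
    if J < 3:
        raise ValueError("Brant's test needs at least 3 outcome categories")
    K = len(terms)
    code = records[outcome].map({c: i for i, c in enumerate(cats)})
    if code.isna().any():
        raise ValueError("outcome contains values outside the stated categories")
    code = code.to_numpy()
    X = sm.add_constant(design_matrix(records, terms), has_constant="add").to_numpy()
    n, p = X.shape  # p = K + 1 including intercept

    betas = []
    pis = []
    for j in range(J - 1):
        z = (code > j).astype(float)
        if z.sum() == 0 or z.sum() == n:
            raise BrantUntestableError(
                f"cumulative split above {cats[j]!r} has no events on one side"
            )
        try:
            res = _fit_logit(z, X)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise BrantUntestableError(str(exc)) from exc
        _check_converged_params(np.asarray(res.params), bool(res.mle_retvals["converged"]))
        betas.append(np.asarray(res.params))
        pis.append(np.asarray(res.predict(X)))

    # Joint covariance of the stacked estimates: for m <= l,
    # cov(b_m, b_l) = (X'W_mm X)^-1 X'W_ml X (X'W_ll X)^-1 with
    # W_ml = diag(pi_l - pi_m * pi_l)  (pi_m >= pi_l for m <= l).
    xtwx_inv = []
    for j in range(J - 1):
        w = pis[j] * (1 - pis[j])
        xtwx_inv.append(np.linalg.inv(X.T @ (X * w[:, None])))
    V = np.zeros(((J - 1) * p, (J - 1) * p))
    for m in range(J - 1):
        for l in range(m, J - 1):
            w_ml = pis[l] - pis[m] * pis[l]
            block = xtwx_inv[m] @ (X.T @ (X * w_ml[:, None])) @ xtwx_inv[l]
            V[m * p : (m + 1) * p, l * p : (l + 1) * p] = block
            if l != m:
                V[l * p : (l + 1) * p, m * p : (m + 1) * p] = block.T
    beta_all = np.concatenate(betas)

    # Keep only the slopes (drop each equation's intercept, position 0).
    keep = [j * p + k for j in range(J - 1) for k in range(1, p)]
    b = beta_all[keep]
    Vb = V[np.ix_(keep, keep)]

    def _wald(contrasts: np.ndarray) -> tuple[float, int, float]:
        d = contrasts @ b
        cov = contrasts @ Vb @ contrasts.T
        chi2 = float(d @ np.linalg.solve(cov, d))
        df = contrasts.shape[0]
        return chi2, df, float(stats.chi2.sf(chi2, df))

    # Omnibus: equation j vs equation 0 for every slope.
    D = np.zeros(((J - 2) * K, (J - 1) * K))
    for j in range(1, J - 1):
        for k in range(K):
            row = (j - 1) * K + k
            D[row, k] = 1.0
            D[row, j * K + k] = -1.0
    chi2, df, pval = _wald(D)

    per_var = []
    for k, t in enumerate(terms):
        Dk = np.zeros((J - 2, (J - 1) * K))
        for j in range(1, J - 1):
            Dk[j - 1, k] = 1.0
            Dk[j - 1, j * K + k] = -1.0
        c2, d_, pv = _wald(Dk)
        per_var.append({"term": t, "chi_square": c2, "df": d_, "p_value": pv})

    return BrantResult(
        chi_square=chi2,
        df=df,
        p_value=pval,
        per_variable=pd.DataFrame(per_var).set_index("term"),
    )


def fitted_profile_probabilities(
    binary: BinaryModelFit,
    ordinal: OrdinalModelFit,
    profiles: Sequence[AttributeProfile],
) -> pd.DataFrame:
    """Model-predicted probabilities for each profile (one row per profile).

    Columns: the profile attributes, the predicted consecutive-positivity
    probability from the binary model, and the predicted four-category
    weeks distribution from the ordinal model (which, with age-only
    terms, is identical for profiles sharing an age group).
    """
    rows = []
    for pr in profiles:
        dist = ordinal.predict_category_distribution(pr)
        row = {
            "age_group": pr.age_group,
            "pain": int(pr.pain),
            "smoker": int(pr.smoker),
            "childhood_stressor": int(pr.childhood_stressor),
            "p_followup_positive": binary.predict_probability(pr),
        }
        for cat, p in zip(WEEKS_CATEGORIES, dist):
            row[f"p_weeks_{cat}"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows)
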