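"""Outcome-association models for comparing health metrics.

Each metric (per-SD log-DM, allostatic load, self-assessed health) is
entered into a regression against a health outcome:

* mortality — Cox proportional hazards with *age as the timescale*
  (left truncation at entry age, event/censoring at exit age, Efron tie
  handling), so age is adjusted nonparametrically by the baseline hazard;
* frailty criteria count and comorbidity count — Poisson regression;
* individual chronic diseases (CVD, diabetes) — logistic regression.

Non-Cox models adjust for age through a cubic B-spline basis (df
configurable, default 5).  Three covariate sets mirror common practice:
(1) age + sex; (2) plus physical/cognitive function (walk time, MMSE);
(3) plus socio-economic status (education, race when present).  Reported
effects are exponentiated coefficients of the metric — hazard, rate, or
odds ratios per SD — with Wald 95% intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import ConfigurationError, FitError, SchemaError, ValidationError

FAMILY_FOR_OUTCOME = {
    "mortality": "cox_age_timescale",
    "frailty_count": "poisson",
    "comorbidity_count": "poisson",
    "cvd": "logistic",
    "diabetes": "logistic",
}

OUTCOME_COLUMN = {
    "mortality": "event",
    "frailty_count": "frailty",
    "comorbidity_count": "comorbidity_count",
    "cvd": "cvd",
    "diabetes": "diabetes",
}

#: additional covariates per covariate set (beyond age and sex)
COVARIATE_SETS: Dict[int, List[str]] = {
    1: [],
    2: ["walk_time", "mmse"],
    3: ["education"],
}

_SEPARATION_SE = 50.0  # Wald SE beyond which a logistic fit is flagged as separated


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    family: Optional[str] = None
    covariate_set: int = 1
    age_spline_df: int = 5

    def __post_init__(self) -> None:
        if self.outcome not in FAMILY_FOR_OUTCOME:
            raise ConfigurationError(
                f"unknown outcome {self.outcome!r}; expected one of {sorted(FAMILY_FOR_OUTCOME)}"
            )
        fam = self.family or FAMILY_FOR_OUTCOME[self.outcome]
        if fam != FAMILY_FOR_OUTCOME[self.outcome]:
            raise ConfigurationError(
                f"family {fam!r} does not match outcome {self.outcome!r} "
                f"(expected {FAMILY_FOR_OUTCOME[self.outcome]!r})"
            )
        object.__setattr__(self, "family", fam)
        if self.covariate_set not in COVARIATE_SETS:
            raise ConfigurationError("covariate_set must be 1, 2 or 3")


@dataclass
class AssociationResult:
    metric: str
    outcome: str
    family: str
    covariate_set: int
    effect: float  # hazard/rate/odds ratio per SD
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    status: str = "ok"
    spec: Optional[ModelSpec] = None

    def __post_init__(self) -> None:
        if self.status == "ok":
            if not (self.ci_low <= self.effect <= self.ci_high):
                raise ValidationError("effect must lie inside its confidence interval")
            if not self.effect > 0:
                raise ValidationError("ratio-scale effect must be positive")


def _covariate_columns(cohort: Cohort, spec: ModelSpec) -> List[str]:
    cols = []
    if "sex" in cohort.data.columns and cohort.data["sex"].nunique() > 1:
        cols.append("sex")
    for c in COVARIATE_SETS[spec.covariate_set]:
        if c in cohort.data.columns:
            cols.append(c)
    if spec.covariate_set == 3 and "race" in cohort.data.columns:
        if cohort.data["race"].nunique() > 1:
            cols.append("race")
    return cols


def _design(df: pd.DataFrame, metric: str, covariates: Sequence[str]) -> pd.DataFrame:
    """Numeric design block: metric + covariates, categoricals dummy-coded."""
    out = pd.DataFrame(index=df.index)
    out[metric] = pd.to_numeric(df[metric], errors="coerce")
    for c in covariates:
        col = df[c]
        num = pd.to_numeric(col, errors="coerce")
        if num.notna().all():
            out[c] = num
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=c, drop_first=True)
            for d in dummies.columns:
                out[d] = dummies[d].astype(float)
    return out


def _bspline_basis(age: np.ndarray, df_: int) -> np.ndarray:
    """Cubic B-spline basis for age with interior knots at quantiles."""
    from scipy.interpolate import BSpline

    degree = 3
    n_interior = max(df_ - degree, 0)
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(age, qs) if n_interior else np.array([])
    lo, hi = float(age.min()), float(age.max())
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    n_basis = len(knots) - degree - 1
    basis = np.empty((age.size, n_basis))
    for i in range(n_basis):
        coef = np.zeros(n_basis)
        coef[i] = 1.0
        basis[:, i] = BSpline(knots, coef, degree, extrapolate=False)(np.clip(age, lo, hi))
    return basis[:, 1:]  # drop one column; the model has its own intercept


def fit_association(
    cohort: Cohort,
    spec: ModelSpec,
    metric: str,
) -> AssociationResult:
    """Fit one metric-outcome model and return the per-SD ratio with Wald CI.

    The metric column is expected to be already scaled per SD
    (:func:`dsign.dysregulation.score_per_sd`); complete cases only.
    """
    import statsmodels.api as sm

    if metric not in cohort.data.columns:
        raise SchemaError(f"metric column {metric!r} absent from cohort")
    covariates = _covariate_columns(cohort, spec)

    if spec.family == "cox_age_timescale":
        from lifelines import CoxPHFitter

        needed = ["age", "event", "event_age", metric] + covariates
        missing = [c for c in needed if c not in cohort.data.columns]
        if missing:
            raise SchemaError(f"columns absent for mortality model: {missing}")
        df = cohort.data[needed].dropna().copy()
        df["event_age"] = pd.to_numeric(df["event_age"])
        df["age"] = pd.to_numeric(df["age"])
        if (df["event_age"] <= df["age"]).any():
            raise ValidationError("entry age must precede event/censoring age for every row")
        design = _design(df, metric, covariates)
        design["age"] = df["age"].astype(float)
        design["event_age"] = df["event_age"].astype(float)
        design["event"] = pd.to_numeric(df["event"]).astype(int)
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(design, duration_col="event_age", event_col="event", entry_col="age")
        except Exception as exc:  # lifelines raises ConvergenceError and others
            raise FitError(f"Cox model failed: {exc}") from exc
        row = cph.summary.loc[metric]
        return AssociationResult(
            metric=metric,
            outcome=spec.outcome,
            family=spec.family,
            covariate_set=spec.covariate_set,
            effect=float(row["exp(coef)"]),
            ci_low=float(row["exp(coef) lower 95%"]),
            ci_high=float(row["exp(coef) upper 95%"]),
            p_value=float(row["p"]),
            n_used=len(design),
            spec=spec,
        )

    ycol = OUTCOME_COLUMN[spec.outcome]
    needed = ["age", ycol, metric] + covariates
    missing = [c for c in needed if c not in cohort.data.columns]
    if missing:
        raise SchemaError(f"columns absent for {spec.outcome!r} model: {missing}")
    df = cohort.data[needed].dropna().copy()
    y = pd.to_numeric(df[ycol]).to_numpy(dtype=float)
    design = _design(df, metric, covariates)
    age = pd.to_numeric(df["age"]).to_numpy(dtype=float)
    spline = _bspline_basis(age, spec.age_spline_df)
    for i in range(spline.shape[1]):
        design[f"age_bs{i + 1}"] = spline[:, i]
    X = sm.add_constant(design.astype(float), has_constant="add")

    family = sm.families.Poisson() if spec.family == "poisson" else sm.families.Binomial()
    status = "ok"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=family).fit()
    except Exception as exc:
        raise FitError(f"{spec.family} model failed: {exc}") from exc
    if not np.isfinite(res.params[metric]) or not np.isfinite(res.bse[metric]):
        raise FitError(f"{spec.family} model produced non-finite estimates")
    if spec.family == "logistic" and res.bse[metric] > _SEPARATION_SE:
        status = "separation_suspected"

    ci = res.conf_int().loc[metric]
    return AssociationResult(
        metric=metric,
        outcome=spec.outcome,
        family=spec.family,
        covariate_set=spec.covariate_set,
        effect=float(np.exp(res.params[metric])),
        ci_low=float(np.exp(ci[0])),
        ci_high=float(np.exp(ci[1])),
        p_value=float(res.pvalues[metric]),
        n_used=len(df),
        status=status,
        spec=spec,
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_metrics(
    cohort: Cohort,
    metrics: Sequence[str],
    outcomes: Sequence[Union[str, ModelSpec]],
    covariate_sets: Sequence[int] = (1, 2, 3),
) -> pd.DataFrame:
    """Fit the full cross-product metrics x outcomes x covariate sets.

    Individual cell failures are recorded in the ``status`` column and the
    run continues.  No multiplicity correction is applied; significance
    stars mark p < 0.05 / 0.01 / 0.001.
    """
    rows = []
    for metric in metrics:
        for out in outcomes:
            base = out if isinstance(out, ModelSpec) else ModelSpec(outcome=out)
            for cs in covariate_sets:
                spec = replace(base, covariate_set=cs)
                try:
                    res = fit_association(cohort, spec, metric)
                    rows.append(
                        {
                            "metric": metric,
                            "outcome": spec.outcome,
                            "family": spec.family,
                            "covset": cs,
                            "effect": res.effect,
                            "ci_low": res.ci_low,
                            "ci_high": res.ci_high,
                            "p": res.p_value,
                            "stars": _stars(res.p_value),
                            "n_used": res.n_used,
                            "status": res.status,
                        }
                    )
                except Exception as exc:
                    rows.append(
                        {
                            "metric": metric,
                            "outcome": spec.outcome,
                            "family": spec.family or "",
                            "covset": cs,
                            "effect": np.nan,
                            "ci_low": np.nan,
                            "ci_high": np.nan,
                            "p": np.nan,
                            "stars": "",
                            "n_used": 0,
                            "status": f"failed: {exc}",
                        }
                    )
    return pd.DataFrame(rows)
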