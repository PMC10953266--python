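"""Cohort-level statistics on fitted parameters and cognition scores.

Group comparisons use ordinary least squares with age as a covariate
(between-subject, one observation per subject): least-squares means are
the model predictions at the pooled mean age, tested via the group
coefficient, Bonferroni-corrected over the seven-parameter family.
Cohen's D is the raw standardized mean difference (patient minus
control, pooled SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from sgm.model import PARAM_NAMES, SGMParams

__all__ = [
    "SubjectRecord",
    "ParamComparison",
    "GroupStats",
    "RegressionReport",
    "group_compare",
    "regress_cognition",
    "cohort_to_frame",
]

GROUPS = ("control", "patient")
COGNITION_PARAMS = ("tau_G", "tau_e", "g_ii")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's covariates, fitted parameters, and spectral features."""

    id: str
    group: str
    age: float
    params: SGMParams
    mmse: float | None = None
    cdr_sob: float | None = None
    tau_acf: float | None = None
    peak_cfs: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not (self.age > 0 and np.isfinite(self.age)):
            raise ValueError(f"age must be positive and finite, got {self.age}")
        if self.mmse is not None and not (0 <= self.mmse <= 30):
            raise ValueError(f"MMSE {self.mmse} outside [0, 30]")
        if self.cdr_sob is not None and self.cdr_sob < 0:
            raise ValueError(f"CDR-SOB {self.cdr_sob} negative")


@dataclass(frozen=True)
class ParamComparison:
    """Age-adjusted group comparison for a single parameter."""

    parameter: str
    ls_mean_control: float
    ls_mean_patient: float
    ci_control: tuple[float, float]
    ci_patient: tuple[float, float]
    t_stat: float
    p_raw: float
    p_bonferroni: float
    cohen_d: float


@dataclass(frozen=True)
class GroupStats:
    comparisons: dict[str, ParamComparison] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, c in self.comparisons.items():
            rows.append(
                {
                    "parameter": name,
                    "ls_mean_control": c.ls_mean_control,
                    "ls_mean_patient": c.ls_mean_patient,
                    "ci_control_lo": c.ci_control[0],
                    "ci_control_hi": c.ci_control[1],
                    "ci_patient_lo": c.ci_patient[0],
                    "ci_patient_hi": c.ci_patient[1],
                    "t_stat": c.t_stat,
                    "p_raw": c.p_raw,
                    "p_bonferroni": c.p_bonferroni,
                    "cohen_d": c.cohen_d,
                }
            )
        return pd.DataFrame(rows).set_index("parameter")


@dataclass(frozen=True)
class RegressionReport:
    mode: str
    outcome: str
    results: dict


def cohort_to_frame(table: list[SubjectRecord]) -> pd.DataFrame:
    """Flatten subject records to one row per subject."""
    rows = []
    for rec in table:
        row = {
            "id": rec.id,
            "group": rec.group,
            "age": rec.age,
            "mmse": rec.mmse,
            "cdr_sob": rec.cdr_sob,
            "tau_acf": rec.tau_acf,
        }
        row.update(rec.params.to_dict())
        if rec.peak_cfs is not None:
            row["first_cf"], row["second_cf"] = rec.peak_cfs
        rows.append(row)
    return pd.DataFrame(rows)


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    return float(
        np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    )


def cohens_d(patient: np.ndarray, control: np.ndarray) -> float:
    """Standardized mean difference, patient minus control, pooled SD."""
    return float((patient.mean() - control.mean()) / _pooled_sd(patient, control))


def group_compare(
    table: list[SubjectRecord],
    n_comparisons: int = len(PARAM_NAMES),
    d_on_residuals: bool = False,
) -> GroupStats:
    """Age-adjusted comparison of each fitted parameter between groups.

    Per parameter: OLS ``value ~ group + age``; LS-means and their 95%
    CIs are model predictions at the pooled mean age; the unpaired t and
    p come from the group coefficient; Bonferroni multiplies raw p by
    ``n_comparisons`` (capped at 1). ``d_on_residuals`` computes Cohen's
    D on age-adjusted residuals instead of raw values.
    """
    df = cohort_to_frame(table)
    for g in GROUPS:
        if (df["group"] == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 subjects")
    is_patient = (df["group"] == "patient").astype(float).to_numpy()
    age = df["age"].to_numpy(float)
    mean_age = age.mean()
    comparisons = {}
    for name in PARAM_NAMES:
        y = df[name].to_numpy(float)
        X = sm.add_constant(np.column_stack([is_patient, age]))
        fit = sm.OLS(y, X).fit()
        t_stat = float(fit.tvalues[1])
        p_raw = float(fit.pvalues[1])
        x_ctrl = np.array([1.0, 0.0, mean_age])
        x_pat = np.array([1.0, 1.0, mean_age])
        pred = fit.get_prediction(np.vstack([x_ctrl, x_pat]))
        means = pred.predicted_mean
        ci = pred.conf_int(alpha=0.05)
        if d_on_residuals:
            resid = y - fit.params[2] * (age - mean_age)
            d = cohens_d(resid[is_patient == 1], resid[is_patient == 0])
        else:
            d = cohens_d(y[is_patient == 1], y[is_patient == 0])
        comparisons[name] = ParamComparison(
            parameter=name,
            ls_mean_control=float(means[0]),
            ls_mean_patient=float(means[1]),
            ci_control=(float(ci[0, 0]), float(ci[0, 1])),
            ci_patient=(float(ci[1, 0]), float(ci[1, 1])),
            t_stat=t_stat,
            p_raw=p_raw,
            p_bonferroni=float(min(1.0, n_comparisons * p_raw)),
            cohen_d=d,
        )
    return GroupStats(comparisons)


def regress_cognition(
    table: list[SubjectRecord],
    mode: str = "univariate",
    outcome: str = "mmse",
    predictors: tuple[str, ...] = COGNITION_PARAMS,
) -> RegressionReport:
    """Associations between fitted parameters and a cognition score.

    ``univariate``: the outcome regressed on each predictor separately;
    Bonferroni over the number of predictors. ``multivariate``: one
    model with all predictors plus age; reports per-predictor p values,
    model r, adjusted r-squared and F.
    """
    df = cohort_to_frame(table)
    df = df[df[outcome].notna()]
    if len(df) < 10:
        raise ValueError(
            f"cognition scores present for only {len(df)} subjects (need >= 10)"
        )
    y = df[outcome].to_numpy(float)
    if mode == "univariate":
        results = {}
        for name in predictors:
            x = df[name].to_numpy(float)
            X = sm.add_constant(x)
            fit = sm.OLS(y, X).fit()
            p_raw = float(fit.pvalues[1])
            results[name] = {
                "slope": float(fit.params[1]),
                "intercept": float(fit.params[0]),
                "r": float(np.sign(fit.params[1]) * np.sqrt(fit.rsquared)),
                "p_raw": p_raw,
                "p_bonferroni": float(min(1.0, len(predictors) * p_raw)),
                "ci": tuple(float(v) for v in fit.conf_int()[1]),
                "n": int(len(df)),
            }
        return RegressionReport("univariate", outcome, results)
    if mode == "multivariate":
        cols = list(predictors) + ["age"]
        X = sm.add_constant(df[cols].to_numpy(float))
        fit = sm.OLS(y, X).fit()
        results = {
            "coefficients": {c: float(b) for c, b in zip(cols, fit.params[1:])},
            "p_values": {c: float(p) for c, p in zip(cols, fit.pvalues[1:])},
            "model_r": float(np.sqrt(fit.rsquared)),
            "adj_r_squared": float(fit.rsquared_adj),
            "f_stat": float(fit.fvalue),
            "n": int(len(df)),
        }
        return RegressionReport("multivariate", outcome, results)
    raise ValueError(f"unknown mode {mode!r}")
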