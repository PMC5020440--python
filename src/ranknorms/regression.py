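"""The four-model OLS ladder, collinearity diagnostics and descriptives.

Model 1 regresses a judgment on absolute BrAC alone; Model 2 on relative
rank alone; Model 3 on both plus the distance between the respondent's
BrAC and their reference-group mean (the central-tendency rival to the
rank account); Model 4 adds the sensitivity covariates (session
duration, after-11pm flag, gender, FAST score, age).  The substantive
test is Model 3/4: under the rank hypothesis the rank coefficient
survives joint adjustment while the absolute-BrAC coefficient does not.

Fits are ordinary least squares via statsmodels with normal-theory 95%
CIs; standardized betas come from refitting on z-scored variables
(binary predictors z-scored like continuous ones, n-1 denominator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

#: Predictor sets of the regression ladder, in reporting order.
MODEL_PREDICTORS: dict[int, tuple[str, ...]] = {
    1: ("brac",),
    2: ("rank",),
    3: ("brac", "rank", "group_mean_distance"),
    4: ("brac", "rank", "group_mean_distance",
        "duration", "after_11pm", "male", "fast", "age"),
}

OUTCOME_LABELS = {
    "judge_drunk": "Perceived drunkenness",
    "judge_extreme": "Extreme drinking",
    "judge_health15y": "Long-term health",
    "judge_cirrhosis15y": "Liver cirrhosis",
}


class SingularDesignError(ValueError):
    """The design matrix is rank-deficient (perfectly collinear columns)."""


@dataclass(frozen=True)
class ModelSpec:
    """One rung of the ladder: which outcome on which predictors."""

    model_id: int
    outcome: str
    predictors: tuple[str, ...] = ()

    def __post_init__(self):
        if self.model_id not in MODEL_PREDICTORS:
            raise ValueError(f"model_id must be 1-4, got {self.model_id!r}")
        if not self.predictors:
            object.__setattr__(self, "predictors", MODEL_PREDICTORS[self.model_id])


@dataclass
class ModelFit:
    """A fitted model: coefficients, standardized betas, CIs, R2, VIF."""

    spec: ModelSpec
    n_used: int
    params: pd.DataFrame  # index: const + predictors; columns: b, beta, ci_low, ci_high, p, stars
    r_squared: float
    vif: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def coef(self) -> pd.Series:
        return self.params["b"]

    def to_dict(self) -> dict:
        return {
            "model_id": self.spec.model_id,
            "outcome": self.spec.outcome,
            "n_used": int(self.n_used),
            "r_squared": float(self.r_squared),
            "terms": {
                str(name): {
                    "b": _f(row["b"]),
                    "beta": _f(row["beta"]),
                    "ci95": [_f(row["ci_low"]), _f(row["ci_high"])],
                    "p": _f(row["p"]),
                    "stars": row["stars"],
                }
                for name, row in self.params.iterrows()
            },
            "vif": {str(k): _f(v) for k, v in self.vif.items()},
        }


def _f(x) -> float | None:
    x = float(x)
    return None if np.isnan(x) else x


def significance_stars(p: float) -> str:
    """The conventional star band: * p<.05, ** p<.01, *** p<.001."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(ddof=1)
    return (a - a.mean()) / sd if sd > 0 else np.zeros_like(a)


def fit_model(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit one ladder model by OLS with listwise deletion.

    Returns unstandardized b with normal-theory 95% CIs and p-values,
    standardized beta, R2, and per-predictor VIF (models with >= 2
    predictors).  A constant outcome yields zero slopes and R2 = 0; a
    rank-deficient design raises :class:`SingularDesignError` naming the
    collinear columns.
    """
    cols = [spec.outcome, *spec.predictors]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"data lacks columns {missing}")
    complete = data[cols].dropna()
    n_dropped = len(data) - len(complete)
    if n_dropped:
        logger.info(
            "model %d (%s): listwise deletion dropped %d of %d rows",
            spec.model_id, spec.outcome, n_dropped, len(data),
        )
    n_used = len(complete)
    if n_used <= len(spec.predictors) + 1:
        raise ValueError(
            f"model {spec.model_id} ({spec.outcome}): {n_used} complete rows "
            f"cannot identify {len(spec.predictors)} predictors plus intercept"
        )

    y = complete[spec.outcome].to_numpy(float)
    X = complete[list(spec.predictors)].to_numpy(float)
    exog = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise SingularDesignError(
            f"design matrix is rank-deficient among columns "
            f"{_collinear_columns(complete[list(spec.predictors)])}"
        )

    index = ["const", *spec.predictors]
    if y.std(ddof=1) == 0:
        params = pd.DataFrame(
            {
                "b": [y[0]] + [0.0] * len(spec.predictors),
                "beta": [0.0] * (1 + len(spec.predictors)),
                "ci_low": [y[0]] + [0.0] * len(spec.predictors),
                "ci_high": [y[0]] + [0.0] * len(spec.predictors),
                "p": np.nan,
            },
            index=index,
        )
        params["stars"] = ""
        return ModelFit(spec=spec, n_used=n_used, params=params, r_squared=0.0,
                        vif=_maybe_vif(complete, spec))

    res = sm.OLS(y, exog).fit()
    ci = res.conf_int(alpha=0.05)

    z_exog = sm.add_constant(
        np.column_stack([_zscore(X[:, j]) for j in range(X.shape[1])]),
        has_constant="add",
    )
    beta = sm.OLS(_zscore(y), z_exog).fit().params

    params = pd.DataFrame(
        {
            "b": res.params,
            "beta": beta,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p": res.pvalues,
        },
        index=index,
    )
    params["stars"] = [significance_stars(p) for p in params["p"]]
    return ModelFit(
        spec=spec,
        n_used=n_used,
        params=params,
        r_squared=float(res.rsquared),
        vif=_maybe_vif(complete, spec),
    )


def _maybe_vif(complete: pd.DataFrame, spec: ModelSpec) -> pd.Series:
    if len(spec.predictors) < 2:
        return pd.Series(dtype=float)
    return compute_vif(complete[list(spec.predictors)])


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns involved in an exact linear dependence (via the VIF scan)."""
    flagged = []
    for col in X.columns:
        others = X.drop(columns=col)
        if others.shape[1] == 0:
            continue
        r2 = _aux_r_squared(X[col].to_numpy(float), others.to_numpy(float))
        if r2 > 1 - 1e-10:
            flagged.append(col)
    return flagged or list(X.columns)


def _aux_r_squared(y: np.ndarray, X: np.ndarray) -> float:
    """R2 of the auxiliary regression y ~ 1 + X (for the VIF formula)."""
    exog = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(exog, y, rcond=None)
    resid = y - exog @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return 0.0
    return 1.0 - float(np.sum(resid**2)) / tss


def compute_vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, VIF_i = 1 / (1 - R2_i).

    R2_i is from regressing predictor i on all the others (with an
    intercept).  Perfect collinearity is reported as ``inf`` rather than
    raised, so the diagnostic can still be printed.
    """
    if design.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    out = {}
    mat = design.to_numpy(float)
    for j, col in enumerate(design.columns):
        y = mat[:, j]
        if y.std(ddof=1) == 0:
            raise ValueError(f"predictor {col!r} has zero variance")
        X = np.delete(mat, j, axis=1)
        r2 = _aux_r_squared(y, X)
        out[col] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with mid-rank ties; NaN if either input
    is constant (the correlation is then undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def pooled_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int]:
    """Pooled-variance two-sample t statistic from summary statistics.

    Returns (t, df).  Used e.g. to check the printed gender contrast in
    BrAC against its reported means, SDs and group sizes.
    """
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), int(df)


#: (column, label, kind) rows of the descriptive table, in reporting order.
_TABLE1_ROWS = [
    ("judge_drunk", "Perceived drunkenness", "mean"),
    ("judge_extreme", "Extreme drinking", "mean"),
    ("judge_health15y", "Long-term health", "mean"),
    ("judge_cirrhosis15y", "Liver cirrhosis", "mean"),
    ("brac_ug_per_100ml", "BrAC (ug alcohol/100 ml breath)", "mean"),
    ("session_duration_h", "Session duration (hours)", "mean"),
    ("survey_after_23h", "Proportion surveyed after 11 pm", "proportion"),
    ("gender", "Proportion male", "proportion_male"),
    ("fast_score", "FAST", "mean"),
    ("age_years", "Age (years)", "mean"),
]


def descriptives(pool: pd.DataFrame, subsample: pd.DataFrame) -> dict:
    """Descriptive summary: per-variable mean/SD (or proportion) for the
    judgment subsample, plus the pool-level gender t-test and location
    ANOVA on positive BrAC.

    The gender and location contrasts use pool members with BrAC > 0
    (zero readings index non-drinkers, excluded from the intoxication
    descriptives though not from ranking).
    """
    if len(pool) == 0 or len(subsample) == 0:
        raise ValueError("pool and subsample must be nonempty")
    rows = []
    for col, label, kind in _TABLE1_ROWS:
        if col not in subsample.columns:
            continue
        if kind == "proportion_male":
            vals = (subsample["gender"] == "M").astype(float)
        else:
            vals = subsample[col].astype(float)
        vals = vals.dropna()
        if kind == "mean":
            rows.append({"variable": label, "value": vals.mean(), "sd": vals.std(ddof=1)})
        else:
            rows.append({"variable": label, "value": vals.mean(), "sd": np.nan})
    table1 = pd.DataFrame(rows)

    drinkers = pool[pool["brac_ug_per_100ml"] > 0]
    male = drinkers.loc[drinkers["gender"] == "M", "brac_ug_per_100ml"]
    female = drinkers.loc[drinkers["gender"] == "F", "brac_ug_per_100ml"]
    if len(male) > 1 and len(female) > 1:
        t, p = stats.ttest_ind(male, female, equal_var=True)
        gender_t = {
            "male_mean": float(male.mean()), "male_sd": float(male.std(ddof=1)),
            "female_mean": float(female.mean()), "female_sd": float(female.std(ddof=1)),
            "n_male": int(len(male)), "n_female": int(len(female)),
            "t": float(t), "p": float(p),
        }
    else:
        gender_t = {"t": float("nan"), "p": float("nan")}

    by_loc = [g["brac_ug_per_100ml"].to_numpy(float)
              for _, g in drinkers.groupby("location")]
    if len(by_loc) >= 2 and all(len(g) > 1 for g in by_loc):
        F, p = stats.f_oneway(*by_loc)
        location_anova = {
            "F": float(F), "p": float(p),
            "df_between": len(by_loc) - 1,
            "df_within": int(sum(len(g) for g in by_loc) - len(by_loc)),
        }
    else:
        location_anova = {"F": float("nan"), "p": float("nan")}

    return {"table1": table1, "gender_t": gender_t, "location_anova": location_anova}


def fit_ladder(
    data: pd.DataFrame,
    outcomes: Sequence[str] = tuple(OUTCOME_LABELS),
    models: Sequence[int] = (1, 2, 3, 4),
) -> dict[str, dict[int, ModelFit]]:
    """Fit every requested (outcome, model) pair; skip outcomes absent
    from the data."""
    fits: dict[str, dict[int, ModelFit]] = {}
    for out in outcomes:
        if out not in data.columns or data[out].notna().sum() == 0:
            logger.warning("outcome %s absent or empty; skipped", out)
            continue
        fits[out] = {m: fit_model(data, ModelSpec(m, out)) for m in models}
    return fits
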