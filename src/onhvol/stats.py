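"""Association models between OCT volumes and intracranial pressure.

Three analyses operate on a tidy per-eye cohort table:

* a linear GEE with identity link, exchangeable working correlation and
  robust (sandwich) standard errors, clustered by subject, which uses both
  eyes while accounting for their within-subject correlation;
* an ordinary least-squares regression on one eye per subject (right eye
  unless only the left is available), with the Pearson correlation of the
  outcome and predictor;
* plain Pearson correlations between two volume measures.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .types import ModelFit, ModelFitTerm, ValidationError

REQUIRED_COLUMNS = ("subject_id", "eye", "icp_cmH2O")


def _check_table(table: pd.DataFrame, columns: list[str]) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValidationError(f"cohort table lacks columns: {missing}")
    for c in columns:
        if not np.all(np.isfinite(table[c].to_numpy(dtype=float))):
            raise ValidationError(f"non-finite values in column {c!r}")


def _wald_terms(
    names: list[str], params: np.ndarray, bse: np.ndarray
) -> list[ModelFitTerm]:
    """Wald 95% CIs and two-sided normal p-values from robust SEs.

    A zero standard error (perfect fit) yields a degenerate CI at the
    coefficient and p = 0 for a nonzero coefficient (p = 1 at zero).
    """
    z = scipy.stats.norm.ppf(0.975)
    terms = []
    for name, b, se in zip(names, params, bse):
        if se > 0:
            p = 2.0 * scipy.stats.norm.sf(abs(b) / se)
        else:
            p = 1.0 if b == 0 else 0.0
        terms.append(ModelFitTerm(name, float(b), float(b - z * se), float(b + z * se), float(p)))
    return terms


def fit_gee(
    table: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    cluster: str = "subject_id",
    correlation: str = "exchangeable",
) -> ModelFit:
    """Identity-link linear GEE of an outcome on predictors, clustered.

    Uses an exchangeable working correlation by default (independence is
    available for sensitivity analysis) and robust sandwich standard
    errors.  If the response is fit perfectly (zero residual variance) the
    exchangeable correlation parameter is unidentified, so the model is
    refit under working independence, which leaves the coefficients of an
    exact fit unchanged.
    """
    _check_table(table, [outcome, *predictors])
    groups = table[cluster]
    if groups.nunique() < 2:
        raise ValidationError("GEE requires at least 2 clusters")
    y = table[outcome].to_numpy(dtype=float)
    X = sm.add_constant(table[predictors].astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValidationError("singular design matrix")

    structures = {
        "exchangeable": sm.cov_struct.Exchangeable,
        "independence": sm.cov_struct.Independence,
    }
    if correlation not in structures:
        raise ValidationError(f"unknown working correlation {correlation!r}")

    names = ["intercept", *predictors]

    # a perfect linear fit leaves the working correlation unidentified (and
    # the sandwich degenerate); report the exact coefficients with zero SEs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ols = sm.OLS(y, X).fit()
    if np.max(np.abs(ols.resid)) <= 1e-8 * max(1.0, float(np.max(np.abs(y)))):
        params = np.where(np.abs(ols.params) < 1e-10, 0.0, ols.params)
        return ModelFit(
            terms=_wald_terms(names, params, np.zeros_like(params)),
            outcome=outcome,
            predictors=list(predictors),
            cluster=cluster,
            correlation_structure="degenerate (exact fit)",
            n_obs=len(table),
            n_clusters=int(groups.nunique()),
        )

    def _fit(struct_name: str):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GEE(
                y, X, groups=groups, family=sm.families.Gaussian(),
                cov_struct=structures[struct_name](),
            )
            return model.fit(), struct_name

    res, used = _fit(correlation)
    if not (np.all(np.isfinite(res.params)) and np.all(np.isfinite(res.bse))):
        res, used = _fit("independence")

    return ModelFit(
        terms=_wald_terms(names, np.asarray(res.params), np.asarray(res.bse)),
        outcome=outcome,
        predictors=list(predictors),
        cluster=cluster,
        correlation_structure=used,
        n_obs=len(table),
        n_clusters=int(groups.nunique()),
    )


def select_one_eye(table: pd.DataFrame) -> pd.DataFrame:
    """One row per subject: the right eye, unless only the left is present."""
    _check_table(table, ["icp_cmH2O"])

    def pick(g: pd.DataFrame) -> pd.DataFrame:
        od = g[g["eye"] == "OD"]
        return od.iloc[:1] if len(od) else g.iloc[:1]

    return (
        table.groupby("subject_id", group_keys=False, sort=True)[table.columns]
        .apply(pick)
        .reset_index(drop=True)
    )


def one_eye_regression(
    table: pd.DataFrame, outcome: str, predictor: str
) -> ModelFit:
    """OLS of outcome on a single predictor, one eye per subject.

    Returns the slope with its Wald 95% CI and p-value, plus the Pearson
    correlation between outcome and predictor on the retained eyes.
    """
    _check_table(table, [outcome, predictor])
    sub = select_one_eye(table)
    if len(sub) < 3:
        raise ValidationError("one-eye regression needs >= 3 subjects")
    y = sub[outcome].to_numpy(dtype=float)
    X = sm.add_constant(sub[[predictor]].astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.OLS(y, X).fit()
    if np.std(y) > 0 and np.std(sub[predictor]) > 0:
        r = float(scipy.stats.pearsonr(sub[predictor], y).statistic)
    else:
        r = float("nan")
    return ModelFit(
        terms=_wald_terms(
            ["intercept", predictor], np.asarray(res.params), np.asarray(res.bse)
        ),
        outcome=outcome,
        predictors=[predictor],
        cluster=None,
        correlation_structure=None,
        n_obs=len(sub),
        n_clusters=len(sub),
        pearson_r=r,
    )


def pairwise_correlation(
    table: pd.DataFrame, var_a: str, var_b: str, one_eye: bool = True
) -> tuple[float, float]:
    """Pearson correlation (rho, two-sided p) between two measures."""
    _check_table(table, [var_a, var_b])
    sub = select_one_eye(table) if one_eye else table
    if len(sub) < 3:
        raise ValidationError("correlation needs >= 3 observations")
    a = sub[var_a].to_numpy(dtype=float)
    b = sub[var_b].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValidationError("zero variance in a correlated variable")
    res = scipy.stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def two_sample_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Plain two-sample t-test (statistic, two-sided p)."""
    res = scipy.stats.ttest_ind(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


def model_fit_frame(fit: ModelFit) -> pd.DataFrame:
    """Coefficient table mirroring the published layout: one row per term
    with estimate, 95% CI bounds and p-value."""
    rows = [
        {
            "term": t.name,
            "coef": t.coef,
            "ci_low": t.ci_low,
            "ci_high": t.ci_high,
            "p_value": t.p_value,
        }
        for t in fit.terms
    ]
    df = pd.DataFrame(rows)
    df.insert(0, "outcome", fit.outcome)
    if fit.pearson_r is not None:
        df["pearson_r"] = fit.pearson_r
    return df
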