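"""Predictor models of the BP response and the same-signal interaction test.

The predictor models are ordinary least squares of one method's
pretreatment-adjusted response on subject covariates. Backward elimination
follows the trial's rule: within a drug arm, a candidate is retained only
if it is significant (p < 0.05) for both the systolic and diastolic
responses; the weakest candidate (largest minimum p-value across the two
endpoints) is dropped one at a time and the models refit.

The same-signal test asks whether the covariate effects depend on the
measurement method. The four adjusted responses per subject are stacked
long (4 rows per subject) and modeled as covariates + method indicators +
covariate-by-method interactions, estimated with a working within-subject
correlation (exchangeable by default) and a cluster-robust sandwich
covariance; the joint Wald test that all interaction coefficients vanish
is the test of the same-signal null. The sandwich covariance keeps the
test valid whichever working structure is used.

Because the joint test has many degrees of freedom (3 per covariate) and
the sandwich is itself estimated from the clusters, the asymptotic
chi-square reference over-rejects in finite samples. By default the test
therefore uses the Mancl-DeRouen bias-corrected sandwich and refers the
Wald statistic to a Hotelling T-squared (scaled F) distribution with the
number of clusters minus the number of mean parameters as the nominal
sample size; ``reference="chisq"`` restores the asymptotic reference.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import CollinearDesignError, ValidationError
from .prep import ResponsePanel

_COND_THRESHOLD = 1e10


@dataclass
class PredictorModelResult:
    """OLS fit of one method's adjusted response on covariates."""

    drug: str
    endpoint: str
    method: str
    predictors: tuple[str, ...]
    params: pd.Series       # mmHg per unit, incl. intercept ("const")
    bse: pd.Series
    pvalues: pd.Series
    r_squared: float
    n_subjects: int

    def table(self) -> pd.DataFrame:
        """Publication-style coefficient table (beta, SE, p)."""
        return pd.DataFrame({"beta": self.params, "se": self.bse, "p": self.pvalues})


@dataclass
class SameSignalTestResult:
    """Joint Wald test of all covariate-by-method interactions."""

    wald_statistic: float
    df: int
    p_value: float
    interaction_params: pd.Series
    interaction_bse: pd.Series
    working_correlation: str
    n_subjects: int
    reference: str = "hotelling"

    def to_dict(self) -> dict:
        return {
            "wald_statistic": float(self.wald_statistic),
            "df": int(self.df),
            "p_value": float(self.p_value),
            "interaction_params": {k: float(v) for k, v in self.interaction_params.items()},
            "interaction_bse": {k: float(v) for k, v in self.interaction_bse.items()},
            "working_correlation": self.working_correlation,
            "n_subjects": int(self.n_subjects),
            "reference": self.reference,
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _covariate_matrix(covariates: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    missing = [c for c in names if c not in covariates.columns]
    if missing:
        raise ValidationError(f"covariate table lacks columns {missing}")
    X = covariates[list(names)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("covariates contain non-finite entries")
    return X


def fit_predictor_model(panel: ResponsePanel, covariates: pd.DataFrame,
                        method: str = "home",
                        predictors: Sequence[str] | None = None) -> PredictorModelResult:
    """OLS of one method's adjusted response on the given covariates."""
    if method not in panel.methods:
        raise ValidationError(f"method must be one of {panel.methods}, got {method!r}")
    if len(covariates) != panel.n_subjects:
        raise ValidationError("covariates must have one row per panel subject")
    names = tuple(predictors) if predictors is not None else tuple(covariates.columns)
    y = panel.values(adjusted=True)[:, panel.methods.index(method)]
    X = _covariate_matrix(covariates, names)
    exog = sm.add_constant(X, has_constant="add")
    cond = np.linalg.cond(exog)
    if cond > _COND_THRESHOLD:
        raise CollinearDesignError(
            f"design condition number {cond:.3g} exceeds {_COND_THRESHOLD:.0e} "
            f"(predictors {names})")
    res = sm.OLS(y, exog).fit()
    index = ["const", *names]
    return PredictorModelResult(
        drug=panel.drug, endpoint=panel.endpoint, method=method,
        predictors=names,
        params=pd.Series(res.params, index=index),
        bse=pd.Series(res.bse, index=index),
        pvalues=pd.Series(res.pvalues, index=index),
        r_squared=float(res.rsquared),
        n_subjects=panel.n_subjects,
    )


def backward_eliminate(panel_systolic: ResponsePanel, panel_diastolic: ResponsePanel,
                       covariates: pd.DataFrame,
                       candidates: Sequence[str] | None = None,
                       method: str = "home",
                       alpha: float = 0.05,
                       ) -> tuple[PredictorModelResult, PredictorModelResult]:
    """Backward stepwise elimination over one drug arm's two endpoints.

    A candidate is retained only while significant (p < ``alpha``) for both
    the systolic and diastolic adjusted responses; otherwise the candidate
    with the largest minimum p-value across the two endpoints is dropped
    and both models are refit. Returns the final (systolic, diastolic)
    model pair; if nothing survives, intercept-only models are returned
    with a warning.
    """
    if panel_systolic.n_subjects != panel_diastolic.n_subjects:
        raise ValidationError("systolic and diastolic panels must share subjects")
    if not np.array_equal(panel_systolic.subject_ids, panel_diastolic.subject_ids):
        raise ValidationError("systolic and diastolic panels must share subjects")
    current = list(candidates) if candidates is not None else list(covariates.columns)
    while True:
        if not current:
            warnings.warn("no candidates survive backward elimination; "
                          "returning intercept-only models")
            empty = covariates.iloc[:, :0]
            return (fit_predictor_model(panel_systolic, empty, method, ()),
                    fit_predictor_model(panel_diastolic, empty, method, ()))
        res_s = fit_predictor_model(panel_systolic, covariates, method, current)
        res_d = fit_predictor_model(panel_diastolic, covariates, method, current)
        worst_p = {c: max(res_s.pvalues[c], res_d.pvalues[c]) for c in current}
        if all(p < alpha for p in worst_p.values()):
            return res_s, res_d
        min_p = {c: min(res_s.pvalues[c], res_d.pvalues[c]) for c in current}
        failing = [c for c in current if worst_p[c] >= alpha]
        drop = max(failing, key=lambda c: min_p[c])
        current.remove(drop)


def _stacked_design(panel: ResponsePanel, covariates: pd.DataFrame,
                    names: Sequence[str]):
    """Long-format response/design for the interaction model.

    Columns: intercept | covariates (k) | method dummies (m-1, first method
    reference) | covariate-by-method interactions (k*(m-1), covariate-major).
    """
    Y = panel.values(adjusted=True)
    n, m = Y.shape
    X = _covariate_matrix(covariates, names)
    k = X.shape[1]
    y = Y.ravel()                               # subject-major
    groups = np.repeat(np.arange(n), m)
    Xl = np.repeat(X, m, axis=0)
    D = np.tile(np.eye(m)[:, 1:], (n, 1))       # method dummies
    inter = (Xl[:, :, None] * D[:, None, :]).reshape(n * m, k * (m - 1))
    exog = np.column_stack([np.ones(n * m), Xl, D, inter])
    dummy_names = [f"method[{mm}]" for mm in panel.methods[1:]]
    inter_names = [f"{c}:method[{mm}]" for c in names for mm in panel.methods[1:]]
    colnames = ["const", *names, *dummy_names, *inter_names]
    return y, exog, groups, colnames, len(inter_names)


def _cluster_robust_ols(y, exog, groups):
    """OLS coefficients with a cluster-robust sandwich covariance.

    Computed from the normal equations directly so that a zero-residual
    (noise-free) dataset yields an exactly zero sandwich rather than NaNs.
    """
    XtX = exog.T @ exog
    beta = np.linalg.solve(XtX, exog.T @ y)
    resid = y - exog @ beta
    # per-cluster score sums; clusters are contiguous blocks
    scores = exog * resid[:, None]
    n_clusters = groups[-1] + 1
    cluster_scores = np.zeros((n_clusters, exog.shape[1]))
    np.add.at(cluster_scores, groups, scores)
    meat = cluster_scores.T @ cluster_scores
    bread = np.linalg.inv(XtX)
    return beta, bread @ meat @ bread


def _wald_p_value(wald: float, df: int, n_clusters: int, n_params: int,
                  reference: str) -> tuple[float, str]:
    """P-value for a cluster-robust Wald statistic.

    ``"hotelling"`` refers wald * (m - df + 1) / (df * m) to F(df, m - df + 1)
    with m = clusters - mean parameters, the small-sample reference for a
    quadratic form in an estimated covariance; falls back to the asymptotic
    chi-square when the clusters cannot support it.
    """
    if reference == "hotelling":
        m = n_clusters - n_params
        if m - df + 1 >= 2:
            f_stat = wald * (m - df + 1) / (df * m)
            return float(stats.f.sf(f_stat, df, m - df + 1)), "hotelling"
        warnings.warn("too few clusters for the Hotelling reference; using chi-square")
    return float(stats.chi2.sf(wald, df)), "chisq"


def same_signal_test(panel: ResponsePanel, covariates: pd.DataFrame,
                     predictors: Sequence[str] | None = None,
                     working: str = "exchangeable",
                     reference: str = "hotelling") -> SameSignalTestResult:
    """Joint Wald test that covariate effects are method-independent."""
    if len(panel.methods) < 2:
        raise ValidationError("same-signal test needs at least 2 methods")
    if working not in ("exchangeable", "independence"):
        raise ValidationError(f"working must be 'exchangeable' or 'independence', got {working!r}")
    if reference not in ("hotelling", "chisq"):
        raise ValidationError(f"reference must be 'hotelling' or 'chisq', got {reference!r}")
    names = tuple(predictors) if predictors is not None else tuple(covariates.columns)
    y, exog, groups, colnames, n_inter = _stacked_design(panel, covariates, names)
    used = working
    params = cov = None
    # a (numerically) perfect fit has no sampling variability: the sandwich is
    # exactly zero and the iterative GEE would only add floating-point noise
    beta_ols, cov_ols = _cluster_robust_ols(y, exog, groups)
    rss = float(np.sum((y - exog @ beta_ols) ** 2))
    if rss <= 1e-10 * max(float(np.var(y) * len(y)), 1.0):
        params, cov = beta_ols, np.zeros_like(cov_ols)
        used = "independence"
    if params is None and working == "exchangeable":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GEE(y, exog, groups=groups,
                               cov_struct=sm.cov_struct.Exchangeable())
                res = model.fit(maxiter=20, cov_type="bias_reduced")
            params = np.asarray(res.params)
            cov = np.asarray(res.cov_robust_bc)
            if not (np.isfinite(params).all() and np.isfinite(cov).all()):
                raise ValueError("non-finite GEE estimates")
        except Exception:
            warnings.warn("exchangeable working-correlation estimation failed; "
                          "falling back to independence")
            used = "independence"
            params = cov = None
    if params is None:
        params, cov = beta_ols, cov_ols
    idx = np.arange(exog.shape[1] - n_inter, exog.shape[1])
    b = params[idx]
    V = cov[np.ix_(idx, idx)]
    # pseudo-inverse so an exactly-zero sandwich (noise-free data with true
    # null) yields wald = 0, p = 1 instead of a failure
    wald = float(b @ np.linalg.pinv(V) @ b)
    p_value, used_ref = _wald_p_value(wald, n_inter, panel.n_subjects,
                                      exog.shape[1], reference)
    return SameSignalTestResult(
        wald_statistic=wald, df=n_inter, p_value=p_value,
        interaction_params=pd.Series(b, index=[colnames[i] for i in idx]),
        interaction_bse=pd.Series(np.sqrt(np.maximum(np.diag(V), 0.0)),
                                  index=[colnames[i] for i in idx]),
        working_correlation=used,
        n_subjects=panel.n_subjects,
        reference=used_ref,
    )
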