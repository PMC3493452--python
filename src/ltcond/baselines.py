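"""Comparison statistics: logistic regression and interaction tests.

These are the standard case-control tests the LT statistic is benchmarked
against: logistic regression of status on genotype with or without covariates
(LogR / LogR+Cov), the 2-dof joint test of genetic main effect and gene x
covariate interaction (G+GxE), the 1-dof interaction-only test, logistic
regression restricted to a case subset (LogRSub), the case-only interaction
test, and an inverse-probability-weighted logistic variant for non-randomly
sampled designs.  The headline statistic is the likelihood-ratio chi-square;
Wald is available as an option.  Maximum likelihood is by IRLS (statsmodels).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .assoc import chisq_df_convert

__all__ = [
    "GlmFit",
    "BaselineResult",
    "logr_test",
    "g_gxe_test",
    "gxe_1dof_test",
    "logr_subset_test",
    "case_only_test",
]

_SEPARATION_BOUND = 50.0
_MAXITER = 100
_TOL = 1e-8


@dataclass(frozen=True)
class GlmFit:
    coefficients: np.ndarray
    stderrs: np.ndarray
    loglike: float
    converged: bool
    iterations: int


@dataclass(frozen=True)
class BaselineResult:
    statistic: float
    p_value: float
    df: int
    effect: float  # log-OR of the genotype term
    stderr: float
    converged: bool
    statistic_1dof: float | None = None  # df-converted equivalent when df > 1


def _as_design(*cols) -> np.ndarray:
    arrs = [np.atleast_2d(np.asarray(c, dtype=float)) for c in cols if c is not None]
    arrs = [a.T if a.shape[0] == 1 else a for a in arrs]
    n = arrs[0].shape[0]
    return np.column_stack([np.ones(n)] + arrs)


def _fit_logit(y, X, weights=None) -> GlmFit:
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    y = np.asarray(y, dtype=float)
    if weights is None:
        mod = sm.GLM(y, X, family=sm.families.Binomial())
    else:
        mod = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=np.asarray(weights, float))
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = mod.fit(maxiter=_MAXITER, tol=_TOL)
        separated = any(issubclass(w.category, PerfectSeparationWarning) for w in caught)
    except Exception:
        k = X.shape[1]
        return GlmFit(np.full(k, np.nan), np.full(k, np.nan), np.nan, False, _MAXITER)
    coefs = np.asarray(res.params, dtype=float)
    converged = (
        bool(res.converged)
        and not separated
        and np.all(np.abs(coefs) < _SEPARATION_BOUND)
    )
    return GlmFit(coefs, np.asarray(res.bse, float), float(res.llf), converged,
                  int(getattr(res, "fit_history", {}).get("iteration", 0) or 0))


def _check_status(z) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if not np.isin(z, (0.0, 1.0)).all():
        raise ValueError("status must be binary 0/1")
    if z.min() == z.max():
        raise ValueError("both cases and controls must be present")
    return z


def _undefined(df: int) -> BaselineResult:
    return BaselineResult(float("nan"), float("nan"), df, float("nan"), float("nan"), False)


def logr_test(
    status,
    genotype,
    covariates=None,
    weights=None,
    statistic: str = "lrt",
) -> BaselineResult:
    """Logistic regression chi-square for the genotype term.

    With ``covariates`` the covariate main effects are present in both the
    null and alternative models (LogR+Cov).  With ``weights`` the fit is
    inverse-probability weighted and the reported statistic is a Wald test
    with a robust (sandwich) variance, as likelihood ratios are not
    interpretable under weighting.
    """
    z = _check_status(status)
    g = np.asarray(genotype, dtype=float)
    if statistic not in ("lrt", "wald"):
        raise ValueError(f"unknown statistic {statistic!r}")

    X_full = _as_design(g, covariates)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        mod = sm.GLM(z, X_full, family=sm.families.Binomial(), var_weights=w)
        try:
            res = mod.fit(maxiter=_MAXITER, tol=_TOL, cov_type="HC0")
        except Exception:
            return _undefined(1)
        if not res.converged or np.abs(res.params).max() > _SEPARATION_BOUND:
            return _undefined(1)
        beta, se = float(res.params[1]), float(res.bse[1])
        stat = (beta / se) ** 2
        return BaselineResult(stat, float(stats.chi2.sf(stat, 1)), 1, beta, se, True)

    full = _fit_logit(z, X_full)
    if not full.converged:
        return _undefined(1)
    if statistic == "wald":
        beta, se = full.coefficients[1], full.stderrs[1]
        stat = float((beta / se) ** 2)
    else:
        X_null = _as_design(covariates) if covariates is not None else np.ones((len(z), 1))
        null = _fit_logit(z, X_null)
        if not null.converged:
            return _undefined(1)
        stat = float(2.0 * (full.loglike - null.loglike))
        stat = max(stat, 0.0)
    return BaselineResult(
        stat, float(stats.chi2.sf(stat, 1)), 1,
        float(full.coefficients[1]), float(full.stderrs[1]), True,
    )


def g_gxe_test(status, genotype, covariate) -> BaselineResult:
    """2-dof LRT of {genotype, genotype x covariate} jointly.

    The covariate main effect sits in both the null and the alternative; the
    interaction uses the mean-centered covariate.  The df-converted 1-dof
    equivalent is reported alongside.
    """
    z = _check_status(status)
    g = np.asarray(genotype, dtype=float)
    t = np.asarray(covariate, dtype=float)
    tc = t - t.mean()
    full = _fit_logit(z, _as_design(tc, g, g * tc))
    null = _fit_logit(z, _as_design(tc))
    if not (full.converged and null.converged):
        return _undefined(2)
    stat = max(float(2.0 * (full.loglike - null.loglike)), 0.0)
    return BaselineResult(
        stat, float(stats.chi2.sf(stat, 2)), 2,
        float(full.coefficients[2]), float(full.stderrs[2]), True,
        statistic_1dof=float(chisq_df_convert(stat, 2, 1)),
    )


def gxe_1dof_test(status, genotype, covariate) -> BaselineResult:
    """1-dof LRT of the gene x covariate interaction given the main effects.

    Null {1, covariate, genotype}; alternative adds genotype x covariate.  By
    nesting, this equals the G+GxE statistic minus the covariate-adjusted
    LogR statistic exactly.
    """
    z = _check_status(status)
    g = np.asarray(genotype, dtype=float)
    t = np.asarray(covariate, dtype=float)
    tc = t - t.mean()
    full = _fit_logit(z, _as_design(tc, g, g * tc))
    null = _fit_logit(z, _as_design(tc, g))
    if not (full.converged and null.converged):
        return _undefined(1)
    stat = max(float(2.0 * (full.loglike - null.loglike)), 0.0)
    return BaselineResult(
        stat, float(stats.chi2.sf(stat, 1)), 1,
        float(full.coefficients[3]), float(full.stderrs[3]), True,
    )


def logr_subset_test(
    status, genotype, covariate, cutoff: float, direction: str = "below"
) -> BaselineResult:
    """LogR keeping all controls and only cases on one side of a cutoff.

    ``direction="below"`` retains cases with covariate <= cutoff (e.g. the
    genetically enriched low-BMI cases); ``"above"`` the complement.
    """
    z = _check_status(status)
    g = np.asarray(genotype, dtype=float)
    t = np.asarray(covariate, dtype=float)
    if direction not in ("below", "above"):
        raise ValueError(f"unknown direction {direction!r}")
    case_keep = t <= cutoff if direction == "below" else t >= cutoff
    keep = (z == 0) | case_keep
    if not ((z == 1) & case_keep).any():
        raise ValueError("cutoff leaves no cases in the subset")
    return logr_test(z[keep], g[keep])


def case_only_test(covariate_group, genotype) -> BaselineResult:
    """Case-only interaction test: logistic regression of group on genotype.

    ``covariate_group`` is a binary indicator distinguishing the two
    covariate classes among cases (e.g. BMI 35 vs BMI 24).
    """
    grp = np.asarray(covariate_group, dtype=float)
    uniq = np.unique(grp)
    if uniq.size != 2:
        raise ValueError("exactly two covariate groups are required")
    y = (grp == uniq.max()).astype(float)
    return logr_test(y, genotype)
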