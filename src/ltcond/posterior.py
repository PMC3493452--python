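"""Posterior mean residual liability E(eps | z, t).

Given case/control status and covariates, the residual liability eps of a
case is standard normal truncated to the upper tail beyond the individual's
threshold tau, and of a control to the lower tail below tau.  The posterior
means are the truncated-normal means

    cases:    E(eps | eps >= tau) =  phi(tau) / (1 - Phi(tau))
    controls: E(eps | eps <  tau) = -phi(tau) / Phi(tau)

evaluated under the null (gamma = 0), which is where the score test sits.
When a case's covariates are measured at disease onset the liability is known
to sit exactly at the threshold, so E(eps | z=1, t) = tau.

Both tail means are computed on the log scale (log pdf minus log tail mass),
which stays accurate far into the tails (|tau| well beyond 30).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .model import LiabilityModel

__all__ = [
    "Cohort",
    "PosteriorLiability",
    "impute_missing_covariates",
    "posterior_means",
    "upper_tail_mean",
    "lower_tail_mean",
]

MODE_TAIL = "tail"
MODE_ONSET = "onset"


@dataclass(frozen=True)
class Cohort:
    """Case-control samples with covariate values (NaN = missing)."""

    sample_ids: tuple[str, ...]
    status: np.ndarray  # 0 = control, 1 = case
    covariate_names: tuple[str, ...]
    covariates: np.ndarray  # (n_samples, n_covariates), NaN for missing
    onset_flags: tuple[bool, ...] = ()
    imputed_mask: np.ndarray | None = None  # True where a value was imputed

    def __init__(
        self,
        sample_ids: Sequence[str],
        status: Sequence[int],
        covariate_names: Sequence[str] = (),
        covariates: np.ndarray | None = None,
        onset_flags: Sequence[bool] | None = None,
        imputed_mask: np.ndarray | None = None,
    ):
        ids = tuple(str(s) for s in sample_ids)
        z = np.asarray(status, dtype=int)
        if len(ids) == 0:
            raise ValueError("cohort must contain at least one sample")
        if z.shape != (len(ids),):
            raise ValueError("status must have one entry per sample")
        if not np.isin(z, (0, 1)).all():
            raise ValueError("status must be binary 0/1")
        names = tuple(str(n) for n in covariate_names)
        if covariates is None:
            covariates = np.empty((len(ids), 0))
        X = np.asarray(covariates, dtype=float)
        if X.ndim != 2 or X.shape != (len(ids), len(names)):
            raise ValueError("covariate matrix dimensions must match samples x names")
        if onset_flags is None:
            onset_flags = (False,) * len(names)
        flags = tuple(bool(f) for f in onset_flags)
        if len(flags) != len(names):
            raise ValueError("one onset flag per covariate required")
        if imputed_mask is not None:
            imputed_mask = np.asarray(imputed_mask, dtype=bool)
            if imputed_mask.shape != X.shape:
                raise ValueError("imputed_mask must match the covariate matrix shape")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "status", z)
        object.__setattr__(self, "covariate_names", names)
        object.__setattr__(self, "covariates", X)
        object.__setattr__(self, "onset_flags", flags)
        object.__setattr__(self, "imputed_mask", imputed_mask)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def with_onset_flags(self, onset_covariates: Sequence[str]) -> "Cohort":
        """Return a copy with onset flags set for the named covariates."""
        unknown = set(onset_covariates) - set(self.covariate_names)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")
        flags = tuple(n in set(onset_covariates) for n in self.covariate_names)
        return replace(self, onset_flags=flags)


@dataclass(frozen=True)
class PosteriorLiability:
    """Per-sample thresholds and posterior mean residual liabilities."""

    sample_ids: tuple[str, ...]
    threshold: np.ndarray
    posterior_mean: np.ndarray
    mode: tuple[str, ...]  # "tail" or "onset" per sample


def upper_tail_mean(tau):
    """Mean of a standard normal truncated to [tau, inf): phi(tau)/sf(tau)."""
    tau = np.asarray(tau, dtype=float)
    return np.exp(stats.norm.logpdf(tau) - stats.norm.logsf(tau))


def lower_tail_mean(tau):
    """Mean of a standard normal truncated to (-inf, tau): -phi(tau)/cdf(tau)."""
    tau = np.asarray(tau, dtype=float)
    return -np.exp(stats.norm.logpdf(tau) - stats.norm.logcdf(tau))


def impute_missing_covariates(cohort: Cohort) -> Cohort:
    """Fill missing covariates with the within-status-group mean.

    Missing values in cases get the mean of the covariate among cases with
    observed values, and likewise for controls.  Observed values are left
    untouched; the returned cohort records which entries were imputed so that
    onset-mode substitution can be restricted to genuinely measured values.
    """
    X = cohort.covariates.copy()
    missing = np.isnan(X)
    if not missing.any():
        return replace(cohort, imputed_mask=np.zeros_like(X, dtype=bool))
    z = cohort.status
    for j in range(X.shape[1]):
        for grp in (0, 1):
            sel = z == grp
            miss = missing[:, j] & sel
            if not miss.any():
                continue
            obs = X[sel & ~missing[:, j], j]
            if obs.size == 0:
                grp_name = "cases" if grp else "controls"
                raise ValueError(
                    f"covariate {cohort.covariate_names[j]!r} entirely missing in {grp_name}"
                )
            X[miss, j] = obs.mean()
    return replace(cohort, covariates=X, imputed_mask=missing)


def posterior_means(model: LiabilityModel, cohort: Cohort) -> PosteriorLiability:
    """Per-sample posterior mean residual liability under the null.

    Cases whose onset-flagged covariates were all genuinely observed (not
    imputed) get the exact-onset value ``eps_hat = tau``; all other cases get
    the upper-tail mean and controls the lower-tail mean.
    """
    X = cohort.covariates
    if np.isnan(X).any():
        raise ValueError("cohort has missing covariates; call impute_missing_covariates first")
    if X.shape[1] != model.n_covariates:
        raise ValueError("cohort covariates do not match the model")

    c = np.asarray(model.coefficients)
    tbar = np.asarray(model.reference_means)
    if model.n_covariates:
        tau = -((X - tbar) @ c + model.affine)
    else:
        tau = np.full(cohort.n_samples, -model.affine)
    if not np.all(np.isfinite(tau)):
        raise ValueError("non-finite liability threshold")

    z = cohort.status
    eps = np.where(z == 1, upper_tail_mean(tau), lower_tail_mean(tau))

    onset = np.asarray(cohort.onset_flags, dtype=bool)
    modes = np.full(cohort.n_samples, MODE_TAIL, dtype=object)
    if onset.any():
        if cohort.imputed_mask is not None:
            observed = ~cohort.imputed_mask[:, onset].any(axis=1)
        else:
            observed = np.ones(cohort.n_samples, dtype=bool)
        exact = (z == 1) & observed
        eps = np.where(exact, tau, eps)
        modes[exact] = MODE_ONSET
    return PosteriorLiability(
        sample_ids=cohort.sample_ids,
        threshold=tau,
        posterior_mean=eps,
        mode=tuple(modes),
    )
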