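"""LTPub: fit liability-threshold parameters from published prevalence data.

Published disease prevalences K_i at covariate values t_i are mapped to the
liability scale through the standard-normal quantile function,

    Phi^{-1}(K_i) = c_j * (t_i - tbar_j) + m,

turning the prevalence-curve fit into an ordinary linear least-squares problem
with one slope per covariate and a single shared intercept, solved in closed
form.  With several covariates, each table is read as the marginal prevalence
curve at the means of the other covariates and all slopes are fitted jointly
in one stacked regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .model import LiabilityModel

__all__ = [
    "PrevalenceTable",
    "LTPubFit",
    "fit_ltpub",
    "CorrelationCheck",
    "covariate_correlation_check",
]


@dataclass(frozen=True)
class PrevalenceTable:
    """Published (covariate value, prevalence) observations for one covariate."""

    covariate_name: str
    values: tuple[float, ...]
    prevalences: tuple[float, ...]
    reference_mean: float | None = None

    def __init__(
        self,
        covariate_name: str,
        values: Sequence[float],
        prevalences: Sequence[float],
        reference_mean: float | None = None,
    ):
        v = np.asarray(values, dtype=float)
        k = np.asarray(prevalences, dtype=float)
        if v.shape != k.shape or v.ndim != 1:
            raise ValueError("values and prevalences must be 1-D of equal length")
        if not np.all(np.isfinite(v)):
            raise ValueError("covariate values must be finite")
        if np.any(k <= 0.0) or np.any(k >= 1.0):
            raise ValueError("prevalences must lie strictly in (0, 1)")
        if np.unique(v).size < 2:
            raise ValueError("at least 2 distinct covariate values are required")
        object.__setattr__(self, "covariate_name", str(covariate_name))
        object.__setattr__(self, "values", tuple(v))
        object.__setattr__(self, "prevalences", tuple(k))
        object.__setattr__(
            self, "reference_mean", None if reference_mean is None else float(reference_mean)
        )

    @property
    def effective_mean(self) -> float:
        """Reference mean: explicit override, else the mean of the observed values."""
        if self.reference_mean is not None:
            return self.reference_mean
        return float(np.mean(self.values))


@dataclass(frozen=True)
class LTPubFit:
    """Result of an LTPub fit: the model plus liability-scale residuals."""

    model: LiabilityModel
    residuals: tuple[float, ...]  # observed - fitted, liability scale, stacked
    covariate_of_observation: tuple[str, ...]


def fit_ltpub(
    tables: Sequence[PrevalenceTable] | PrevalenceTable,
    weighting: str = "none",
) -> LTPubFit:
    """Closed-form probit-scale least squares for LT model parameters.

    Parameters
    ----------
    tables
        One :class:`PrevalenceTable` per covariate (or a single table).
    weighting
        ``"none"`` (default) for ordinary least squares on the liability
        scale, or ``"delta"`` for inverse-variance weights proportional to
        ``phi(Phi^{-1}(K))**2 / (K (1 - K))``, the delta-method precision of
        the probit transform under equal-sized prevalence estimates.
    """
    if isinstance(tables, PrevalenceTable):
        tables = [tables]
    tables = list(tables)
    if not tables:
        raise ValueError("at least one prevalence table is required")
    if weighting not in ("none", "delta"):
        raise ValueError(f"unknown weighting {weighting!r}")
    names = [t.covariate_name for t in tables]
    if len(set(names)) != len(names):
        raise ValueError("duplicate covariate names across tables")

    rows_x, rows_y, rows_w, obs_cov = [], [], [], []
    means = [t.effective_mean for t in tables]
    for j, tab in enumerate(tables):
        for t_i, k_i in zip(tab.values, tab.prevalences):
            x = np.zeros(len(tables) + 1)
            x[j] = t_i - means[j]
            x[-1] = 1.0  # shared intercept m
            y = stats.norm.ppf(k_i)
            rows_x.append(x)
            rows_y.append(y)
            obs_cov.append(tab.covariate_name)
            if weighting == "delta":
                rows_w.append(stats.norm.pdf(y) ** 2 / (k_i * (1.0 - k_i)))
            else:
                rows_w.append(1.0)
    X = np.array(rows_x)
    y = np.array(rows_y)
    w = np.array(rows_w)
    sw = np.sqrt(w)
    beta, _, rank, _ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("singular design: prevalence values do not identify the model")
    model = LiabilityModel(
        covariate_names=names,
        coefficients=beta[:-1],
        reference_means=means,
        affine=beta[-1],
    )
    resid = y - X @ beta
    return LTPubFit(model=model, residuals=tuple(resid), covariate_of_observation=tuple(obs_cov))


@dataclass(frozen=True)
class CorrelationCheck:
    """Pairwise squared correlations between cohort covariates."""

    pairs: tuple[tuple[str, str], ...]
    r_squared: tuple[float, ...]
    flagged: tuple[bool, ...]
    threshold: float

    def as_dict(self) -> dict[tuple[str, str], float]:
        return dict(zip(self.pairs, self.r_squared))


def covariate_correlation_check(cohort, threshold: float = 0.05) -> CorrelationCheck:
    """Flag covariate pairs whose r^2 undermines the independent-marginal fit.

    LTPub treats each covariate's prevalence curve as a marginal at the means
    of the others, a good approximation only when covariates are weakly
    correlated (in the source studies every pair had r^2 < 0.026).
    """
    names = list(cohort.covariate_names)
    if len(names) < 2:
        raise ValueError("at least 2 covariates are required")
    X = np.asarray(cohort.covariates, dtype=float)
    complete = ~np.isnan(X).any(axis=1)
    if complete.sum() < 3:
        raise ValueError("at least 3 complete observations are required")
    Xc = X[complete]
    pairs, r2s, flags = [], [], []
    for i, j in combinations(range(len(names)), 2):
        xi, xj = Xc[:, i], Xc[:, j]
        si, sj = xi.std(), xj.std()
        if si == 0.0 or sj == 0.0:
            r2 = float("nan")
        else:
            r2 = float(np.corrcoef(xi, xj)[0, 1] ** 2)
        pairs.append((names[i], names[j]))
        r2s.append(r2)
        flags.append(bool(r2 > threshold) if np.isfinite(r2) else True)
    return CorrelationCheck(
        pairs=tuple(pairs), r_squared=tuple(r2s), flagged=tuple(flags), threshold=threshold
    )
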