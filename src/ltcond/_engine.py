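"""Vectorized replicate engine for stratified case-control-covariate designs.

In a matched design every sample belongs to one of a handful of
(status, covariate) strata, and every statistic considered here depends on the
data only through the per-stratum genotype counts.  Each replicate therefore
collapses to an (n_strata x 3) count table drawn from the model-implied
conditional genotype laws, and all statistics -- the LT trend test and the
logistic-regression family -- are computed from those counts simultaneously
across all replicates with array arithmetic.  The logistic fits use a batched
Newton solver over the collapsed (stratum x genotype) weight patterns; a
single replicate of this path is checked against the per-sample statsmodels
implementations in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .model import (
    LiabilityModel,
    hwe_probabilities,
    case_probabilities_by_genotype,
)
from .posterior import lower_tail_mean, upper_tail_mean

GENOTYPES = np.arange(3.0)


def stratum_status_probs(design, t, status: int) -> np.ndarray:
    """P(status | g, t) for g in {0, 1, 2} under the design's generator."""
    if design.generator == "liability":
        p_case = case_probabilities_by_genotype(
            design.model, t, design.gamma, design.maf, design.interaction
        )
    else:
        lp = design.logit_params
        g_c = GENOTYPES - 2.0 * design.maf
        eta = lp.intercept + lp.genotype_logor * g_c
        if lp.covariate_logors:
            tbar = np.asarray(design.model.reference_means)
            tv = np.atleast_1d(np.asarray(t, dtype=float))
            eta = eta + np.asarray(lp.covariate_logors) @ (tv - tbar)
        p_case = 1.0 / (1.0 + np.exp(-eta))
    return p_case if status == 1 else 1.0 - p_case


def stratum_genotype_probs(design, hwe_approx: bool = False) -> np.ndarray:
    """(S, 3) conditional genotype distributions P(g | z, t) per stratum."""
    hwe = hwe_probabilities(design.maf)
    out = np.empty((len(design.strata), 3))
    for s, st in enumerate(design.strata):
        w = hwe * stratum_status_probs(design, st.covariate_values, st.status)
        total = w.sum()
        if total <= 0.0:
            raise ValueError("infeasible stratum: probability zero under the model")
        p = w / total
        if hwe_approx:
            af = (p[1] + 2.0 * p[2]) / 2.0
            p = hwe_probabilities(af) if 0.0 < af < 1.0 else p
        out[s] = p
    return out


def stratum_posterior_means(analysis_model: LiabilityModel, strata) -> np.ndarray:
    """Posterior mean residual liability per stratum under the analysis model."""
    eps = np.empty(len(strata))
    for s, st in enumerate(strata):
        tau = analysis_model.threshold(st.covariate_values)
        eps[s] = upper_tail_mean(tau) if st.status == 1 else lower_tail_mean(tau)
    return eps


def draw_stratum_counts(probs: np.ndarray, sizes, n_replicates: int, rng) -> np.ndarray:
    """(R, S, 3) multinomial genotype counts per stratum per replicate."""
    S = probs.shape[0]
    out = np.empty((n_replicates, S, 3))
    for s in range(S):
        out[:, s, :] = rng.multinomial(int(sizes[s]), probs[s], size=n_replicates)
    return out


# ---------------------------------------------------------------------------
# statistics from count tables
# ---------------------------------------------------------------------------

def lt_stat_from_counts(counts: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """N * r^2 between genotype and stratum posterior means, per replicate."""
    W = counts
    N = W.sum(axis=(1, 2))
    X = GENOTYPES[None, None, :]
    E = eps[None, :, None]
    sw = lambda a: (W * a).sum(axis=(1, 2))
    mx = sw(X) / N
    me = sw(E) / N
    dx = X - mx[:, None, None]
    de = E - me[:, None, None]
    sxy = sw(dx * de)
    sxx = sw(dx * dx)
    syy = sw(de * de)
    with np.errstate(invalid="ignore", divide="ignore"):
        return N * sxy**2 / (sxx * syy)


def fit_logistic_patterns(
    Xp: np.ndarray, y: np.ndarray, W: np.ndarray, max_iter: int = 40, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Batched Newton fit of weighted logistic models sharing a design.

    Parameters
    ----------
    Xp : (P, K) pattern design matrix
    y : (P,) binary outcome per pattern
    W : (R, P) pattern weights (counts) per replicate

    Returns
    -------
    beta : (R, K) maximum-likelihood coefficients
    loglike : (R,) maximized log-likelihood
    """
    R, P = W.shape
    K = Xp.shape[1]
    beta = np.zeros((R, K))
    for _ in range(max_iter):
        eta = beta @ Xp.T
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = (W * (y - mu)) @ Xp
        Wt = W * mu * (1.0 - mu)
        H = np.einsum("rp,pk,pj->rkj", Wt, Xp, Xp)
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        beta += step
        if np.abs(step).max() < tol:
            break
    eta = beta @ Xp.T
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-300, 1.0 - 1e-16)
    ll = (W * (y * np.log(mu) + (1.0 - y) * np.log1p(-mu))).sum(axis=1)
    return beta, ll


def _loglike_intercept_only(y: np.ndarray, W: np.ndarray) -> np.ndarray:
    n1 = (W * y).sum(axis=1)
    n = W.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.clip(n1 / n, 1e-300, 1.0 - 1e-16)
        return n1 * np.log(p) + (n - n1) * np.log1p(-p)


def logistic_lrt_from_counts(
    counts: np.ndarray,
    statuses: np.ndarray,
    covariate: np.ndarray | None = None,
    interaction: bool = False,
    with_covariate: bool = False,
    keep_strata: np.ndarray | None = None,
    outcome: np.ndarray | None = None,
) -> np.ndarray:
    """Likelihood-ratio chi-square of the genotype block from count tables.

    ``with_covariate`` puts the (mean-centered) covariate main effect in both
    models; ``interaction`` additionally tests genotype x covariate jointly
    with genotype (2 dof).  ``keep_strata`` restricts to a stratum subset and
    ``outcome`` overrides the per-stratum outcome (for the case-only test).
    """
    R = counts.shape[0]
    sel = np.arange(counts.shape[1]) if keep_strata is None else np.asarray(keep_strata)
    sub = counts[:, sel, :]
    S = len(sel)
    W = sub.reshape(R, S * 3)
    y = np.repeat((statuses[sel] if outcome is None else outcome[sel]).astype(float), 3)
    gcol = np.tile(GENOTYPES, S)
    cols_full = [np.ones(S * 3)]
    cols_null = [np.ones(S * 3)]
    if with_covariate or interaction:
        n_per = sub.sum(axis=(0, 2))
        tvals = covariate[sel]
        tbar = (tvals * n_per).sum() / n_per.sum()  # sample mean (fixed by design)
        tc = np.repeat(tvals - tbar, 3)
        cols_full.append(tc)
        cols_null.append(tc)
    cols_full.append(gcol)
    if interaction:
        cols_full.append(gcol * cols_full[1])
    else:
        pass
    X_full = np.column_stack(cols_full)
    if interaction:
        X_null = np.column_stack(cols_null)
        df = 2
    elif with_covariate:
        X_null = np.column_stack(cols_null)
        df = 1
    else:
        X_null = None
        df = 1
    _, ll_full = fit_logistic_patterns(X_full, y, W)
    if X_null is None:
        ll_null = _loglike_intercept_only(y, W)
    else:
        _, ll_null = fit_logistic_patterns(X_null, y, W)
    stat = 2.0 * (ll_full - ll_null)
    return np.maximum(stat, 0.0)


def stats_from_counts(
    counts: np.ndarray,
    design,
    analysis_model: LiabilityModel,
    tests,
    subset_cutoff: float | None = None,
    subset_direction: str = "below",
) -> dict[str, tuple[np.ndarray, int]]:
    """Compute the requested statistics for every replicate's count table.

    Returns a mapping test name -> (statistic array, degrees of freedom).
    For ``g_gxe`` the raw statistic is 2-dof; consumers convert for display.
    """
    strata = design.strata
    statuses = np.array([st.status for st in strata])
    tvals = np.array([st.covariate_values[0] if st.covariate_values else 0.0 for st in strata])
    out: dict[str, tuple[np.ndarray, int]] = {}
    for name in tests:
        if name == "lt":
            eps = stratum_posterior_means(analysis_model, strata)
            out[name] = (lt_stat_from_counts(counts, eps), 1)
        elif name == "logr":
            out[name] = (logistic_lrt_from_counts(counts, statuses), 1)
        elif name == "logr_cov":
            out[name] = (
                logistic_lrt_from_counts(counts, statuses, tvals, with_covariate=True),
                1,
            )
        elif name == "g_gxe":
            out[name] = (
                logistic_lrt_from_counts(counts, statuses, tvals, interaction=True),
                2,
            )
        elif name == "gxe":
            two = logistic_lrt_from_counts(counts, statuses, tvals, interaction=True)
            one = logistic_lrt_from_counts(counts, statuses, tvals, with_covariate=True)
            out[name] = (np.maximum(two - one, 0.0), 1)
        elif name == "logr_sub":
            cutoff, direction = _subset_rule(strata, subset_cutoff, subset_direction)
            case_keep = tvals <= cutoff if direction == "below" else tvals >= cutoff
            keep = np.flatnonzero((statuses == 0) | case_keep)
            if not ((statuses == 1) & case_keep).any():
                raise ValueError("subset cutoff leaves no cases")
            out[name] = (logistic_lrt_from_counts(counts, statuses, keep_strata=keep), 1)
        elif name == "case_only":
            keep = np.flatnonzero(statuses == 1)
            groups = tvals[keep]
            uniq = np.unique(groups)
            if uniq.size != 2:
                raise ValueError("case-only test requires exactly two case covariate groups")
            outcome = (tvals == uniq.max()).astype(float)
            out[name] = (
                logistic_lrt_from_counts(counts, statuses, keep_strata=keep, outcome=outcome),
                1,
            )
        else:
            raise ValueError(f"unknown test {name!r}")
    return out


def _subset_rule(strata, cutoff, direction):
    if cutoff is None:
        case_t = [st.covariate_values[0] for st in strata if st.status == 1]
        lo, hi = min(case_t), max(case_t)
        if lo == hi:
            raise ValueError("subset test needs a cutoff when case covariates are constant")
        cutoff = 0.5 * (lo + hi)
    return float(cutoff), direction
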