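"""LT association statistic: generalized Armitage trend test on posterior means.

The statistic regresses the posterior mean residual liability on genotype
dosage and reports ``N * r^2`` (chi-square, 1 dof).  With nuisance covariates
(e.g. principal components) both genotype and phenotype are residualized on
them first and the statistic is ``(N - K - 1) * r^2`` of the residuals,
generalizing the EIGENSTRAT adjustment.  This equals the score test of the
genotype effect in the liability model evaluated at gamma = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .model import LiabilityModel, StratumSpec, stratum_genotype_distribution
from .posterior import PosteriorLiability

__all__ = [
    "GenotypeMatrix",
    "AssocResult",
    "lt_test",
    "trend_statistic",
    "liability_effect_to_or",
    "chisq_df_convert",
    "meta_combine",
]


@dataclass(frozen=True)
class GenotypeMatrix:
    """Biallelic SNP dosages (samples x SNPs), ALT-allele counted, NaN missing."""

    sample_ids: tuple[str, ...]
    snp_ids: tuple[str, ...]
    dosages: np.ndarray
    chromosomes: tuple[str, ...] = ()
    positions: tuple[int, ...] = ()
    ref: tuple[str, ...] = ()
    alt: tuple[str, ...] = ()

    def __init__(
        self,
        sample_ids: Sequence[str],
        snp_ids: Sequence[str],
        dosages: np.ndarray,
        chromosomes: Sequence[str] | None = None,
        positions: Sequence[int] | None = None,
        ref: Sequence[str] | None = None,
        alt: Sequence[str] | None = None,
    ):
        ids = tuple(str(s) for s in sample_ids)
        snps = tuple(str(s) for s in snp_ids)
        D = np.asarray(dosages, dtype=float)
        if D.ndim != 2 or D.shape != (len(ids), len(snps)):
            raise ValueError("dosage matrix must be samples x SNPs")
        finite = D[np.isfinite(D)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 2.0):
            raise ValueError("dosages must lie in [0, 2]")
        n = len(snps)

        def _meta(x, default):
            if x is None:
                return tuple(default for _ in range(n))
            x = tuple(x)
            if len(x) != n:
                raise ValueError("per-SNP metadata length mismatch")
            return x

        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "snp_ids", snps)
        object.__setattr__(self, "dosages", D)
        object.__setattr__(self, "chromosomes", _meta(chromosomes, "."))
        object.__setattr__(self, "positions", _meta(positions, 0))
        object.__setattr__(self, "ref", _meta(ref, "N"))
        object.__setattr__(self, "alt", _meta(alt, "N"))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass(frozen=True)
class AssocResult:
    snp_id: str
    n_used: int
    statistic: float
    p_value: float
    effect: float  # liability units per ALT allele
    stderr: float
    allele_freq: float
    defined: bool = True
    or_estimate: float | None = None


def _residualize(y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residual of y on [1, C] by least squares."""
    X = np.column_stack([np.ones(len(y)), C])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("singular nuisance design")
    return y - X @ beta


def trend_statistic(
    g: np.ndarray, e: np.ndarray, nuisance: np.ndarray | None = None
) -> tuple[float, float, float, bool]:
    """(chi-square, effect, stderr, defined) for the trend test of e on g."""
    g = np.asarray(g, dtype=float)
    e = np.asarray(e, dtype=float)
    n = len(g)
    k = 0
    if nuisance is not None:
        C = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if C.shape[0] != n:
            C = C.T
        k = C.shape[1]
        g = _residualize(g, C)
        e = _residualize(e, C)
    gc = g - g.mean()
    ec = e - e.mean()
    sgg = gc @ gc
    see = ec @ ec
    if sgg <= 0.0 or see <= 0.0:
        return float("nan"), float("nan"), float("nan"), False
    sge = gc @ ec
    r2 = sge**2 / (sgg * see)
    stat = (n - k - 1) * r2 if k else n * r2
    slope = sge / sgg
    dof = n - k - 2
    sigma2 = max(see - sge**2 / sgg, 0.0) / dof if dof > 0 else float("nan")
    se = float(np.sqrt(sigma2 / sgg)) if dof > 0 else float("nan")
    return float(stat), float(slope), se, True


def lt_test(
    pm: PosteriorLiability,
    geno: GenotypeMatrix,
    nuisance: np.ndarray | None = None,
    missing: str = "complete",
) -> list[AssocResult]:
    """LT association test of posterior mean residual liability per SNP.

    ``missing="complete"`` drops samples with missing dosage per SNP (N
    adjusts accordingly); ``missing="mean"`` imputes the per-SNP mean dosage.
    """
    if pm.sample_ids != geno.sample_ids:
        raise ValueError("posterior means and genotypes are not sample-aligned")
    if missing not in ("complete", "mean"):
        raise ValueError(f"unknown missing-genotype policy {missing!r}")
    e_all = pm.posterior_mean
    C_all = None
    if nuisance is not None:
        C_all = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if C_all.shape[0] != geno.n_samples:
            C_all = C_all.T

    results = []
    for j, snp in enumerate(geno.snp_ids):
        g = geno.dosages[:, j]
        ok = np.isfinite(g)
        if missing == "mean" and (~ok).any() and ok.any():
            g = np.where(ok, g, g[ok].mean())
            ok = np.ones_like(ok)
        if ok.sum() < 3:
            results.append(
                AssocResult(snp, int(ok.sum()), float("nan"), float("nan"),
                            float("nan"), float("nan"), float("nan"), defined=False)
            )
            continue
        gs = g[ok]
        es = e_all[ok]
        Cs = C_all[ok] if C_all is not None else None
        stat, slope, se, defined = trend_statistic(gs, es, Cs)
        af = float(gs.mean() / 2.0)
        p = float(stats.chi2.sf(stat, 1)) if defined else float("nan")
        results.append(
            AssocResult(snp, int(ok.sum()), stat, p, slope, se, af, defined=defined)
        )
    return results


def liability_effect_to_or(
    model: LiabilityModel,
    effect: float,
    maf: float,
    at_covariates: Sequence[float] | None = None,
    control_covariates: Sequence[float] | None = None,
) -> float:
    """Model-implied per-allele odds ratio for a liability-scale effect.

    The OR is the logistic slope of case/control status on allele count fitted
    to the model-implied expected genotype distributions: cases taken at
    ``at_covariates`` (default: the covariate means) and controls at
    ``control_covariates`` (default: same as the cases).  This is an
    approximate conversion; under non-random covariate ascertainment the OR
    depends on which control stratum the cases are compared against.
    """
    if not 0.0 < maf < 1.0:
        raise ValueError("maf must lie strictly in (0, 1)")
    if at_covariates is None:
        at_covariates = model.reference_means
    if control_covariates is None:
        control_covariates = at_covariates
    p_case = stratum_genotype_distribution(
        model, StratumSpec(at_covariates, 1), effect, maf
    ).probabilities
    p_ctrl = stratum_genotype_distribution(
        model, StratumSpec(control_covariates, 0), effect, maf
    ).probabilities
    # weighted logistic fit of status on allele count over the 6 expected cells
    g = np.tile(np.arange(3.0), 2)
    y = np.repeat([1.0, 0.0], 3)
    w = np.concatenate([p_case, p_ctrl])
    X = np.column_stack([np.ones(6), g])
    beta = np.zeros(2)
    for _ in range(100):
        mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
        grad = X.T @ (w * (y - mu))
        H = (X * (w * mu * (1 - mu))[:, None]).T @ X
        step = np.linalg.solve(H, grad)
        beta += step
        if np.abs(step).max() < 1e-12:
            break
    return float(np.exp(beta[1]))


def chisq_df_convert(value: float, from_df: int, to_df: int):
    """Map a chi-square value to the equal-tail-probability value at another dof."""
    value = np.asarray(value, dtype=float)
    if np.any(value < 0):
        raise ValueError("chi-square values must be nonnegative")
    if from_df < 1 or to_df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if from_df == to_df:
        return value if value.ndim else float(value)
    logp = stats.chi2.logsf(value, from_df)
    out = stats.chi2.isf(np.exp(logp), to_df)
    # for very extreme statistics fall back on the asymptotic identity of tails
    extreme = ~np.isfinite(out) | (np.exp(logp) == 0.0)
    if np.any(extreme):
        out = np.where(extreme, _convert_extreme(value, from_df, to_df), out)
    return out if out.ndim else float(out)


def _convert_extreme(value, from_df, to_df):
    # match log tail probabilities by root finding (robust when sf underflows)
    from scipy.optimize import brentq

    value = np.atleast_1d(value)
    out = np.empty_like(value)
    for i, v in enumerate(value):
        logp = float(stats.chi2.logsf(v, from_df))
        if logp == 0.0:
            out[i] = 0.0
            continue
        f = lambda x: stats.chi2.logsf(x, to_df) - logp
        hi = max(-4.0 * logp + 100.0, 10.0)
        out[i] = brentq(f, 0.0, hi, xtol=1e-10, rtol=1e-14)
    return out


def meta_combine(effects: Sequence[float], stderrs: Sequence[float]):
    """Fixed-effect inverse-variance meta-analysis.

    Returns ``(effect, stderr, chisq)`` where chisq is the 1-dof statistic of
    the combined effect.
    """
    b = np.asarray(effects, dtype=float)
    s = np.asarray(stderrs, dtype=float)
    if b.shape != s.shape or b.ndim != 1 or b.size < 1:
        raise ValueError("effects and stderrs must be equal-length 1-D, size >= 1")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / s**2
    beta = float((w * b).sum() / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    return beta, se, (beta / se) ** 2
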