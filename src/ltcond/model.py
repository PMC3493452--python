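"""Liability threshold (LT) disease model.

The model posits an unobserved continuous liability

    phi = sum_j c_j * (t_j - tbar_j) + m + eps,      eps = gamma * g_c + N(0, 1)

where ``t_j`` are clinical covariates (BMI, age, smoking status, ...),
``c_j`` their effects on the liability scale, ``tbar_j`` population reference
means, ``m`` an affine term fixing the disease prevalence at the covariate
means, ``g_c`` the candidate-SNP genotype centered by its population mean
``2*maf``, and ``gamma`` the per-allele genetic effect.  An individual is a
case iff ``phi >= 0``; equivalently iff the residual liability ``eps`` exceeds
the per-individual threshold

    tau(t) = -(sum_j c_j * (t_j - tbar_j) + m).

The residual has unit variance around its genetic component; the total
liability variance ``1 + gamma**2 * Var(g)`` is deliberately not renormalized,
matching how the model parameters are defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LiabilityModel",
    "StratumSpec",
    "GenotypeDistribution",
    "liability_threshold",
    "predict_prevalence",
    "variance_explained",
    "stratum_genotype_distribution",
    "hwe_probabilities",
]


@dataclass(frozen=True)
class LiabilityModel:
    """Parameters of a liability threshold model.

    Parameters
    ----------
    covariate_names
        Ordered covariate identifiers; may be empty (prevalence-only model).
    coefficients
        Per-covariate liability effects ``c_j`` (liability units per covariate
        unit).  Binary covariates (sex, smoking, BMI>30 indicators) enter as
        numeric 0/1.
    reference_means
        Population reference means ``tbar_j`` in covariate units.
    affine
        Affine term ``m``; for diseases with prevalence below 50% it is
        negative, and prevalence at the covariate means equals the
        standard-normal upper-tail probability beyond ``-m``.
    """

    covariate_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    reference_means: tuple[float, ...]
    affine: float

    def __init__(
        self,
        covariate_names: Sequence[str] = (),
        coefficients: Sequence[float] = (),
        reference_means: Sequence[float] = (),
        affine: float = 0.0,
    ):
        object.__setattr__(self, "covariate_names", tuple(str(n) for n in covariate_names))
        object.__setattr__(self, "coefficients", tuple(float(c) for c in coefficients))
        object.__setattr__(self, "reference_means", tuple(float(t) for t in reference_means))
        object.__setattr__(self, "affine", float(affine))
        self._validate()

    def _validate(self) -> None:
        k = len(self.covariate_names)
        if not (len(self.coefficients) == len(self.reference_means) == k):
            raise ValueError(
                "covariate_names, coefficients and reference_means must have equal length"
            )
        vals = np.r_[self.coefficients, self.reference_means, self.affine]
        if not np.all(np.isfinite(vals)):
            raise ValueError("model parameters must be finite")
        k0 = float(stats.norm.sf(-self.affine))
        if not 0.0 < k0 < 1.0:
            raise ValueError(
                f"prevalence at covariate means is {k0}; must lie strictly in (0, 1)"
            )

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    # -- convenience wrappers around the module-level operations -------------
    def threshold(self, t: Sequence[float]) -> float:
        return liability_threshold(self, t)

    def prevalence(self, t: Sequence[float] | None = None) -> float:
        if t is None:
            t = self.reference_means
        return predict_prevalence(self, t)

    def to_dict(self) -> dict:
        return {
            "covariates": [
                {"name": n, "coefficient": c, "mean": t}
                for n, c, t in zip(self.covariate_names, self.coefficients, self.reference_means)
            ],
            "affine": self.affine,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LiabilityModel":
        cov = d.get("covariates", [])
        return cls(
            covariate_names=[c["name"] for c in cov],
            coefficients=[c["coefficient"] for c in cov],
            reference_means=[c["mean"] for c in cov],
            affine=d["affine"],
        )


@dataclass(frozen=True)
class StratumSpec:
    """A (covariate values, case/control status) cell of a stratified design."""

    covariate_values: tuple[float, ...]
    status: int  # 1 = case, 0 = control

    def __init__(self, covariate_values: Sequence[float], status: int):
        vals = tuple(float(v) for v in np.atleast_1d(covariate_values))
        if not np.all(np.isfinite(vals)):
            raise ValueError("covariate values must be finite")
        if int(status) not in (0, 1):
            raise ValueError("status must be 0 (control) or 1 (case)")
        object.__setattr__(self, "covariate_values", vals)
        object.__setattr__(self, "status", int(status))


@dataclass(frozen=True)
class GenotypeDistribution:
    """Distribution of genotype g in {0, 1, 2} copies of the counted allele."""

    probabilities: tuple[float, float, float]

    def __init__(self, probabilities: Sequence[float]):
        p = np.asarray(probabilities, dtype=float)
        if p.shape != (3,):
            raise ValueError("probabilities must have length 3")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "probabilities", tuple(p))

    @property
    def allele_frequency(self) -> float:
        p = self.probabilities
        return (p[1] + 2.0 * p[2]) / 2.0


def _covariate_contribution(model: LiabilityModel, t: Sequence[float]) -> float:
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if t.shape != (model.n_covariates,):
        raise ValueError(
            f"expected {model.n_covariates} covariate values, got {t.shape[0]}"
        )
    if not np.all(np.isfinite(t)):
        raise ValueError("covariate values must be finite")
    if model.n_covariates == 0:
        return 0.0
    c = np.asarray(model.coefficients)
    tbar = np.asarray(model.reference_means)
    return float(c @ (t - tbar))


def liability_threshold(model: LiabilityModel, t: Sequence[float] = ()) -> float:
    """Residual-liability cutoff tau(t) = -(sum_j c_j (t_j - tbar_j) + m).

    An individual with covariates ``t`` is a case iff ``eps >= tau``.
    """
    return -(_covariate_contribution(model, t) + model.affine)


def predict_prevalence(model: LiabilityModel, t: Sequence[float] = ()) -> float:
    """Disease probability at covariates ``t``: P(eps >= tau(t)) under gamma=0."""
    return float(stats.norm.sf(liability_threshold(model, t)))


def variance_explained(
    model: LiabilityModel, covariate_sds: Sequence[float]
) -> np.ndarray:
    """Per-covariate fraction of liability variance explained.

    For covariate ``j`` with standard deviation ``sigma_j`` this is
    ``c_j**2 sigma_j**2 / (1 + sum_k c_k**2 sigma_k**2)``: the covariate terms
    plus the unit-variance residual make up the liability (the small genetic
    term ``gamma**2 Var(g)`` is excluded from the denominator).
    """
    sds = np.atleast_1d(np.asarray(covariate_sds, dtype=float))
    if sds.shape != (model.n_covariates,):
        raise ValueError("one standard deviation per covariate required")
    if np.any(sds < 0):
        raise ValueError("standard deviations must be nonnegative")
    contrib = np.asarray(model.coefficients) ** 2 * sds**2
    return contrib / (1.0 + contrib.sum())


def hwe_probabilities(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities for allele frequency ``maf``."""
    if not 0.0 < maf < 1.0:
        raise ValueError("maf must lie strictly in (0, 1)")
    return np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])


def case_probabilities_by_genotype(
    model: LiabilityModel,
    t: Sequence[float],
    gamma: float,
    maf: float,
    interaction: float = 0.0,
) -> np.ndarray:
    """P(case | g, t) for g in {0, 1, 2}.

    The genotype enters centered by its population mean ``2*maf`` with
    per-allele effect ``gamma`` plus an optional gene-by-covariate interaction
    ``delta * g_c * (t_1 - tbar_1)`` on the first covariate.
    """
    tau = liability_threshold(model, t)
    g_c = np.arange(3.0) - 2.0 * maf
    eff = gamma
    if interaction != 0.0:
        if model.n_covariates == 0:
            raise ValueError("interaction requires at least one covariate")
        t = np.atleast_1d(np.asarray(t, dtype=float))
        eff = gamma + interaction * (t[0] - model.reference_means[0])
    return stats.norm.sf(tau - eff * g_c)


def stratum_genotype_distribution(
    model: LiabilityModel,
    stratum: StratumSpec,
    gamma: float,
    maf: float,
    interaction: float = 0.0,
) -> GenotypeDistribution:
    """Model-implied genotype distribution P(g | status, t) by Bayes' rule.

    Hardy-Weinberg priors on g are reweighted by the normal tail probability
    of the stratum's status at the genotype-shifted threshold
    ``tau(t) - gamma * (g - 2*maf)``.
    """
    p_case = case_probabilities_by_genotype(
        model, stratum.covariate_values, gamma, maf, interaction
    )
    p_status = p_case if stratum.status == 1 else 1.0 - p_case
    w = hwe_probabilities(maf) * p_status
    total = w.sum()
    if total <= 0.0:
        raise ValueError("stratum has probability zero under the model")
    return GenotypeDistribution(w / total)
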