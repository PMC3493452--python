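"""Simulation of case-control datasets under liability-threshold and logit models.

Three ascertainment schemes are supported:

* ``case_control_covariate`` -- matched designs with fixed (status, covariate)
  strata; genotypes are drawn from the exact conditional law P(g | z, t)
  (optionally from Hardy-Weinberg proportions at the stratum allele frequency
  with ``hwe_approx``).
* ``case_control`` -- covariates drawn from a population mixture, status from
  the disease model, with rejection until the target case/control counts are
  reached.
* ``random`` -- covariates from the mixture, status from the model, no
  selection.

The replicate engine (:func:`run_replicates`) evaluates the LT statistic and
the logistic-regression comparison tests over many replicates; for stratified
designs it runs fully vectorized on collapsed genotype-count tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from . import _engine
from .model import LiabilityModel, hwe_probabilities
from .posterior import Cohort, posterior_means
from .assoc import GenotypeMatrix, chisq_df_convert, trend_statistic
from . import baselines as _bl

__all__ = [
    "Stratum",
    "LogitParams",
    "SimDesign",
    "TestSummary",
    "ReplicateSummary",
    "simulate_lt_dataset",
    "simulate_logit_dataset",
    "run_replicates",
    "perturb_model",
    "toy_t2d_design",
    "TEST_NAMES",
]

TEST_NAMES = ("lt", "logr", "logr_cov", "g_gxe", "gxe", "logr_sub", "case_only")


@dataclass(frozen=True)
class Stratum:
    """A sampling stratum: covariate values, target count, optional status."""

    covariate_values: tuple[float, ...]
    count: int
    status: int | None = None

    def __init__(self, covariate_values, count, status=None):
        vals = tuple(float(v) for v in np.atleast_1d(covariate_values))
        if int(count) <= 0:
            raise ValueError("stratum count must be positive")
        if status is not None and int(status) not in (0, 1):
            raise ValueError("status must be 0, 1 or None")
        object.__setattr__(self, "covariate_values", vals)
        object.__setattr__(self, "count", int(count))
        object.__setattr__(self, "status", None if status is None else int(status))


@dataclass(frozen=True)
class LogitParams:
    """Logistic disease model: log-odds linear in centered genotype/covariates."""

    intercept: float = 0.0
    genotype_logor: float = 0.0
    covariate_logors: tuple[float, ...] = ()


@dataclass(frozen=True)
class SimDesign:
    """Generative and ascertainment parameters of a simulation study."""

    model: LiabilityModel
    gamma: float
    maf: float
    strata: tuple[Stratum, ...]
    interaction: float = 0.0
    generator: str = "liability"
    logit_params: LogitParams | None = None
    ascertainment: str = "case_control_covariate"
    n_cases: int | None = None
    n_controls: int | None = None
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.maf < 1.0:
            raise ValueError("maf must lie strictly in (0, 1)")
        if self.generator not in ("liability", "logit"):
            raise ValueError(f"unknown generator {self.generator!r}")
        if self.generator == "logit" and self.logit_params is None:
            raise ValueError("logit generator requires explicit logit_params")
        if self.generator == "logit" and self.interaction != 0.0:
            raise ValueError("interaction is a liability-scale term; unsupported under logit")
        if self.ascertainment not in ("case_control_covariate", "case_control", "random"):
            raise ValueError(f"unknown ascertainment {self.ascertainment!r}")
        if not self.strata:
            raise ValueError("at least one stratum is required")
        has_status = [st.status is not None for st in self.strata]
        if self.ascertainment == "case_control_covariate":
            if not all(has_status):
                raise ValueError("stratified ascertainment requires a status per stratum")
        else:
            if any(has_status):
                raise ValueError(
                    f"{self.ascertainment} ascertainment draws status from the model; "
                    "strata define the covariate mixture and must not carry status"
                )
        if self.ascertainment == "case_control":
            if not (self.n_cases and self.n_controls):
                raise ValueError("case_control ascertainment requires n_cases and n_controls")
        object.__setattr__(self, "strata", tuple(self.strata))


def toy_t2d_design(gamma: float, n_per_stratum: int = 1500, **kwargs) -> SimDesign:
    """The BMI-matched type 2 diabetes toy design.

    3,000 cases and 3,000 BMI-matched controls, half at BMI 24 and half at
    BMI 35, under the fitted model 0.08*(BMI-26.5)-1.44 with a causal SNP of
    population allele frequency 0.5.
    """
    model = LiabilityModel(["bmi"], [0.08], [26.5], -1.44)
    strata = (
        Stratum((24.0,), n_per_stratum, 1),
        Stratum((35.0,), n_per_stratum, 1),
        Stratum((24.0,), n_per_stratum, 0),
        Stratum((35.0,), n_per_stratum, 0),
    )
    return SimDesign(model=model, gamma=gamma, maf=0.5, strata=strata, **kwargs)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _as_rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def _status_prob(design: SimDesign, g: np.ndarray, T: np.ndarray) -> np.ndarray:
    """P(case | g, t) per sample under the design's generator."""
    model = design.model
    g_c = g - 2.0 * design.maf
    tbar = np.asarray(model.reference_means)
    if design.generator == "liability":
        c = np.asarray(model.coefficients)
        tau = -((T - tbar) @ c + model.affine) if model.n_covariates else np.full(len(g), -model.affine)
        eff = design.gamma
        if design.interaction != 0.0:
            eff = design.gamma + design.interaction * (T[:, 0] - tbar[0])
        return stats.norm.sf(tau - eff * g_c)
    lp = design.logit_params
    eta = lp.intercept + lp.genotype_logor * g_c
    if lp.covariate_logors:
        eta = eta + (T - tbar) @ np.asarray(lp.covariate_logors)
    return 1.0 / (1.0 + np.exp(-eta))


def _build_dataset(design, z, T, g) -> tuple[Cohort, GenotypeMatrix]:
    n = len(z)
    ids = tuple(f"s{i+1}" for i in range(n))
    names = design.model.covariate_names
    cohort = Cohort(ids, z.astype(int), names, T[:, : len(names)])
    geno = GenotypeMatrix(ids, ("snp1",), g[:, None].astype(float))
    return cohort, geno


def _simulate(design: SimDesign, rng, rejection_budget: int = 1000):
    if design.ascertainment == "case_control_covariate":
        probs = _engine.stratum_genotype_probs(design)
        zs, Ts, gs = [], [], []
        for s, st in enumerate(design.strata):
            g = rng.choice(3, size=st.count, p=probs[s])
            zs.append(np.full(st.count, st.status))
            Ts.append(np.tile(st.covariate_values, (st.count, 1)))
            gs.append(g)
        return _build_dataset(design, np.concatenate(zs), np.vstack(Ts), np.concatenate(gs))

    # covariate mixture shared by random / case_control schemes
    weights = np.array([st.count for st in design.strata], dtype=float)
    weights /= weights.sum()
    tgrid = np.array([st.covariate_values for st in design.strata])
    hwe = hwe_probabilities(design.maf)

    def forward(n):
        idx = rng.choice(len(weights), size=n, p=weights)
        T = tgrid[idx]
        g = rng.choice(3, size=n, p=hwe)
        z = (rng.random(n) < _status_prob(design, g, T)).astype(int)
        return z, T, g

    if design.ascertainment == "random":
        n = sum(st.count for st in design.strata)
        z, T, g = forward(n)
        return _build_dataset(design, z, T, g)

    need = {1: design.n_cases, 0: design.n_controls}
    got = {1: [], 0: []}
    total_target = design.n_cases + design.n_controls
    drawn = 0
    while any(sum(len(a) for a in got[k]) < need[k] for k in (0, 1)):
        if drawn > rejection_budget * total_target:
            raise RuntimeError("rejection budget exceeded; stratum prevalence too extreme")
        z, T, g = forward(total_target)
        drawn += total_target
        for k in (0, 1):
            sel = z == k
            got[k].append(np.column_stack([T[sel], g[sel]]))
    rows = {k: np.vstack(got[k])[: need[k]] for k in (0, 1)}
    z = np.concatenate([np.ones(need[1], dtype=int), np.zeros(need[0], dtype=int)])
    TG = np.vstack([rows[1], rows[0]])
    return _build_dataset(design, z, TG[:, :-1], TG[:, -1])


def simulate_lt_dataset(design: SimDesign, rng=None) -> tuple[Cohort, GenotypeMatrix]:
    """Draw one dataset under the liability-threshold generator."""
    if design.generator != "liability":
        raise ValueError("design.generator must be 'liability'")
    return _simulate(design, _as_rng(design.seed if rng is None else rng))


def simulate_logit_dataset(design: SimDesign, rng=None) -> tuple[Cohort, GenotypeMatrix]:
    """Draw one dataset under the logistic disease model."""
    if design.generator != "logit":
        raise ValueError("design.generator must be 'logit'")
    return _simulate(design, _as_rng(design.seed if rng is None else rng))


def perturb_model(
    model: LiabilityModel,
    coefficient_factors: float | Sequence[float] = 1.0,
    affine_factor: float = 1.0,
) -> LiabilityModel:
    """Scale model parameters by multiplicative factors (mis-specification studies)."""
    f = np.broadcast_to(np.asarray(coefficient_factors, dtype=float), (model.n_covariates,))
    if not np.all(np.isfinite(f)) or not np.isfinite(affine_factor):
        raise ValueError("factors must be finite")
    return LiabilityModel(
        model.covariate_names,
        tuple(np.asarray(model.coefficients) * f),
        model.reference_means,
        model.affine * affine_factor,
    )


# ---------------------------------------------------------------------------
# replicate engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestSummary:
    name: str
    df: int
    mean_chisq: float  # 1-dof equivalent for multi-dof tests
    mc_se: float
    mean_raw: float  # mean of the raw statistic on its native df
    power: dict  # alpha -> (estimate, binomial se)


@dataclass(frozen=True)
class ReplicateSummary:
    n_replicates: int
    alphas: tuple[float, ...]
    tests: dict  # name -> TestSummary

    def mean(self, name: str) -> float:
        return self.tests[name].mean_chisq

    def power(self, name: str, alpha: float) -> float:
        return self.tests[name].power[alpha][0]


def run_replicates(
    design: SimDesign,
    tests: Sequence[str] = ("lt", "logr"),
    alphas: Sequence[float] = (0.05, 5e-8),
    seed: int | None = None,
    analysis_model: LiabilityModel | None = None,
    hwe_approx: bool = False,
    subset_cutoff: float | None = None,
    chunk_size: int = 200_000,
) -> ReplicateSummary:
    """Simulate ``design.n_replicates`` datasets and summarize each statistic.

    ``analysis_model`` lets the LT statistic be computed under a model other
    than the generative one (parameter mis-specification studies).  Results
    are reproducible per seed; the stratified path is fully vectorized.
    """
    for t in tests:
        if t not in TEST_NAMES:
            raise ValueError(f"unknown test {t!r}; choose from {TEST_NAMES}")
    if design.n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    analysis_model = analysis_model or design.model
    seed = design.seed if seed is None else seed
    alphas = tuple(alphas)

    if design.ascertainment == "case_control_covariate":
        values = _run_stratified(
            design, tests, seed, analysis_model, hwe_approx, subset_cutoff, chunk_size
        )
    else:
        values = _run_per_sample(design, tests, seed, analysis_model, subset_cutoff)

    summaries = {}
    R = design.n_replicates
    for name, (stat, df) in values.items():
        ok = np.isfinite(stat)
        stat_ok = stat[ok]
        n_ok = ok.sum()
        conv = chisq_df_convert(stat_ok, df, 1) if df != 1 else stat_ok
        conv = np.asarray(conv)
        power = {}
        for a in alphas:
            crit = stats.chi2.isf(a, df)
            p_hat = float((stat_ok > crit).mean()) if n_ok else float("nan")
            se = float(np.sqrt(p_hat * (1 - p_hat) / n_ok)) if n_ok else float("nan")
            power[a] = (p_hat, se)
        summaries[name] = TestSummary(
            name=name,
            df=df,
            mean_chisq=float(conv.mean()) if n_ok else float("nan"),
            mc_se=float(conv.std(ddof=1) / np.sqrt(n_ok)) if n_ok > 1 else float("nan"),
            mean_raw=float(stat_ok.mean()) if n_ok else float("nan"),
            power=power,
        )
    return ReplicateSummary(n_replicates=R, alphas=alphas, tests=summaries)


def _run_stratified(design, tests, seed, analysis_model, hwe_approx, subset_cutoff, chunk_size):
    probs = _engine.stratum_genotype_probs(design, hwe_approx=hwe_approx)
    sizes = [st.count for st in design.strata]
    rng = np.random.default_rng(seed)
    R = design.n_replicates
    pieces: dict[str, list[np.ndarray]] = {t: [] for t in tests}
    dfs: dict[str, int] = {}
    done = 0
    while done < R:
        r = min(chunk_size, R - done)
        counts = _engine.draw_stratum_counts(probs, sizes, r, rng)
        vals = _engine.stats_from_counts(
            counts, design, analysis_model, tests, subset_cutoff=subset_cutoff
        )
        for t, (stat, df) in vals.items():
            pieces[t].append(stat)
            dfs[t] = df
        done += r
    return {t: (np.concatenate(pieces[t]), dfs[t]) for t in tests}


def _run_per_sample(design, tests, seed, analysis_model, subset_cutoff):
    """Per-replicate loop for random / case_control ascertainment."""
    R = design.n_replicates
    streams = np.random.SeedSequence(seed).spawn(R)
    out = {t: np.empty(R) for t in tests}
    dfs = {t: (2 if t == "g_gxe" else 1) for t in tests}
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        cohort, geno = _simulate(design, rng)
        g = geno.dosages[:, 0]
        z = cohort.status.astype(float)
        t1 = cohort.covariates[:, 0] if cohort.covariates.shape[1] else None
        for name in tests:
            out[name][i] = _per_sample_stat(
                name, analysis_model, cohort, g, z, t1, subset_cutoff
            )
    return {t: (out[t], dfs[t]) for t in tests}


def _per_sample_stat(name, analysis_model, cohort, g, z, t1, subset_cutoff):
    if name == "lt":
        pm = posterior_means(analysis_model, cohort)
        stat, _, _, defined = trend_statistic(g, pm.posterior_mean)
        return stat if defined else np.nan
    try:
        if name == "logr":
            return _bl.logr_test(z, g).statistic
        if name == "logr_cov":
            return _bl.logr_test(z, g, covariates=t1).statistic
        if name == "g_gxe":
            return _bl.g_gxe_test(z, g, t1).statistic
        if name == "gxe":
            return _bl.gxe_1dof_test(z, g, t1).statistic
        if name == "logr_sub":
            cutoff = subset_cutoff
            if cutoff is None:
                case_t = t1[z == 1]
                cutoff = 0.5 * (case_t.min() + case_t.max())
            return _bl.logr_subset_test(z, g, t1, cutoff).statistic
        if name == "case_only":
            cases = z == 1
            return _bl.case_only_test(t1[cases], g[cases]).statistic
    except ValueError:
        return np.nan
    raise ValueError(f"unknown test {name!r}")
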