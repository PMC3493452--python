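# Methods

## The liability threshold model

`ltcond` models a binary disease phenotype through an unobserved continuous
liability φ = Σ_j c_j (t_j − t̄_j) + m + ε with ε = γ g_c + N(0, 1); an
individual is a case iff φ ≥ 0. The residual ε has unit variance around its
genetic component; the total liability variance 1 + γ² Var(g) is deliberately
not renormalized — the covariate coefficients are defined against the
unit-variance residual, and this convention reproduces the reference stratum
allele frequencies (0.55 / 0.53 / 0.50 / 0.49 in the toy design) that a
variance-standardized genotype effect does not.

Genotype convention: g counts ALT alleles (0/1/2) and enters centered by its
population mean 2·maf; γ is per allele, not per standard deviation. Binary
covariates (sex, smoking status, BMI>30 indicators) enter as numeric 0/1 in
the linear term.

The per-covariate liability variance fraction is c_j² σ_j² / (1 + Σ_k c_k²
σ_k²). The small γ² Var(g) term is excluded from the denominator; with the
per-SNP effects considered here (γ ≤ 0.15, contributing ≤ 1% of variance)
the difference is negligible, and the chosen form matches the reference
variance-explained figures.

## LTPub: fitting from published prevalence data

Published prevalences K_i at covariate values t_i satisfy K_i = Φ̄(τ_i) with
τ_i = −(c (t_i − t̄) + m), hence Φ⁻¹(K_i) = c (t_i − t̄) + m. The fit is
ordinary least squares of the probit-transformed prevalences on centered
covariate values — closed form, no disease-scale search. Choices made here:

- **Weighting.** Unweighted OLS by default. It reproduces the two published
  worked fits (T2D BMI: c = 0.081, m = −1.44 at t̄ = 26.5; prostate age:
  c = 0.0487, m = −2.49 at t̄ = 50). An optional delta-method
  inverse-variance weighting (w ∝ φ(Φ⁻¹(K))² / (K(1−K))) is available but
  off by default, since the provenance-specific normalizer of the original
  objective is not published.
- **Multiple covariates.** Each covariate's table is treated as the marginal
  prevalence curve at the means of the other covariates; all slopes and the
  single intercept are solved jointly in one stacked regression. This is an
  approximation valid for weakly correlated covariates;
  `covariate_correlation_check` flags pairs with r² above 0.05 (the source
  studies saw at most 0.026).
- **Reference means** default to the mean of each table's covariate values
  and can be overridden (the packaged T2D curve pins t̄ = 26.5, as published).
  Mis-specifying the mean shifts m but barely moves the statistic.

## Posterior mean residual liability

Under the null (γ = 0) the residual of a case is standard normal truncated
to [τ, ∞) and of a control to (−∞, τ), with τ = −(Σ c_j (t_j − t̄_j) + m):

- cases: E(ε | z=1, t) = φ(τ)/Φ̄(τ)
- controls: E(ε | z=0, t) = −φ(τ)/Φ(τ)

Posterior means are evaluated at γ = 0 because the association statistic is
a score test at the null. Both tail means are computed as
exp(logpdf − log tail mass) using scipy's log-scale normal CDF/SF, which is
accurate far beyond |τ| = 30 (no 0/0; the case mean obeys
τ < E < τ + 1/τ in the far tail).

**Onset mode.** When a case's covariates are measured at disease onset the
liability is known to sit exactly at the threshold, so E(ε | z=1, t) = τ.
This substitution applies per sample, only to cases, and only when all
onset-flagged covariate values were genuinely observed — a case whose
onset-flagged covariate was imputed falls back to the tail expectation.
Controls always use the tail mean. Missing covariates are imputed with the
within-status-group mean before any of this.

## The LT association statistic

The statistic is N·r²(g, ε̂) — the Armitage trend test with the posterior
mean in place of the 0/1 phenotype — distributed χ²(1) under the null, and
algebraically equal to the score statistic U²/V̂ar(U) with U = Σ g_c,i ε̂_i.
With K nuisance covariates both g and ε̂ are residualized on [1, C] and the
statistic is (N − K − 1)·r², following the EIGENSTRAT convention. Effects
are reported on the liability scale (slope of ε̂ on g) with OLS standard
errors; `meta_combine` performs fixed-effect inverse-variance pooling.

Missing genotypes: per-SNP complete-case analysis by default (N adjusts);
optional per-SNP mean-dosage imputation. Monomorphic SNPs and zero-variance
phenotypes yield a flagged undefined result rather than a 0 statistic.

**OR conversion.** `liability_effect_to_or` reports the logistic slope on
allele count fitted to the model-implied expected genotype distributions of
cases and controls at stated covariate values. Under covariate-dependent
ascertainment the OR depends on which control set the cases are compared
against; the default compares within the same covariate stratum, and an
explicit `control_covariates` argument supports matched/pooled comparisons.
This conversion is an approximation, provided for meta-analysis plumbing.

## Comparison statistics

Logistic-regression fits use IRLS (statsmodels GLM, tolerance 1e−8, max 100
iterations). The headline statistic is the likelihood-ratio χ²; Wald is an
option. The 2-dof G+GxE test compares {1, t} against {1, t, g, g·(t − t̄)};
the 1-dof interaction test compares {1, t, g} against the same alternative,
so it equals G+GxE minus the covariate-adjusted LogR exactly (a nested-LRT
identity; in the matched design the covariate-adjusted and plain LogR are
nearly identical). Perfect separation or non-convergence flags the fit
instead of reporting a misleading p-value. IPW weights must be supplied by
the caller (the true sampling fractions are known in simulation); the
weighted statistic is a Wald test with a sandwich (HC0) variance.

## Simulation engine

For matched (case-control-covariate) designs every statistic considered
depends on the data only through the per-stratum genotype counts, so each
replicate collapses to an (n_strata × 3) multinomial table drawn from the
exact conditional law P(g | z, t) ∝ HWE(g) · P(z | g, t). All statistics are
then computed for ~10⁵ replicates at once: the LT statistic in closed form
from count moments, the logistic family via a batched Newton solver on the
collapsed (stratum × genotype) weight patterns. A replicate of this engine
is tested for equality (to ~1e−8) against the per-sample statsmodels path.
An `hwe_approx` mode draws genotypes from Hardy-Weinberg proportions at the
stratum allele frequency instead; its replicate means are statistically
indistinguishable from the exact mode.

Random and case-control ascertainment use forward per-sample simulation
(covariates from a stated mixture, status from the model, rejection to fixed
case/control counts for the latter, with a capped rejection budget). A logit
generator (log-odds linear in centered genotype and covariates) supports the
model-misspecification experiments. Gene-by-covariate interaction enters the
liability as ε = γ g_c + δ g_c (t − t̄) + N(0,1) with δ user-set.

Randomness: the stratified engine draws all replicate counts from a single
seeded `numpy` Generator in a fixed stratum order, making summaries
byte-reproducible per (design, seed) and independent of chunking; the
per-sample path spawns one child stream per replicate from the master seed.

**Problem sizes.** Replicate studies default to 10⁵ replicates of the
6,000-sample matched toy design (the package's desk-scale default; the
engine completes 10⁵ replicates with two statistics in about two seconds, so
larger runs are a parameter, not a code change). Property tests use 2–3×10⁴
replicates where the asserted margins are many Monte-Carlo standard errors
wide.

## What the replicate averages estimate

A χ²(1) statistic with noncentrality ncp has expectation ncp + 1. The
analytic plug-in statistic at the *expected* stratum genotype counts (e.g.
N·ρ² = 30.35 for the LT test in the toy design at γ = 0.1) is the
noncentrality itself, so honest replicate averages sit one unit above the
plug-in (31.3 for LT, 29.2 for LogR at γ = 0.1), and both are reported by
`reproduce_table2`. The reference table this design reproduces prints values
that coincide with the plug-in expectations at γ = 0.1 but not uniformly
across effect sizes, and its printed power ratio (≈23% at the genome-wide
threshold) corresponds to noncentralities about one unit below the plug-in;
the replicate engine here measures a ≈18% power increase of LT over LogR at
γ = 0.1 under the exact conditional law. The package reports what its own
simulations produce, with Monte-Carlo standard errors, and exposes the
analytic plug-in alongside so both conventions are visible.

What the generator does *not* emulate: linkage disequilibrium, covariate
measurement error, covariate distributions beyond discrete mixtures,
population structure, or relatedness. Passing tests therefore demonstrate
correctness of the statistics under the stated generative law, not
robustness to real-data artifacts (PC adjustment is supported but its
confounding-removal behavior is not simulated here).

## Numerical choices and edge cases

- Normal/χ²/noncentral-χ² machinery is scipy.stats throughout; tail
  quantities on the log scale.
- χ² dof conversion matches upper-tail probabilities; for statistics whose
  tail underflows in double precision it switches to root-finding on the
  log-survival function.
- `ncp_from_power` brackets geometrically and solves by Brent's method to
  1e−12.
- Degenerate inputs (monomorphic SNPs, one-class status, empty case subsets,
  entirely missing covariate-by-status cells, singular designs) raise or
  flag rather than returning spurious numbers.
- Analytic power: the published 43.7%-power example is taken as a
  calibration point (the underlying prevalence/OR mapping is not
  re-derived); inflating the calibrated noncentrality by 1.16 yields 59.8%,
  reproducing the published mapping self-containedly.

## Known limitations

- LTPub does not propagate uncertainty in the published prevalences into the
  association statistic.
- The OR conversion is an expected-count approximation, not a closed-form
  identity; its value depends on the chosen control stratum.
- Multi-SNP / polygenic liability terms are out of scope; one SNP is tested
  at a time against the covariate-informed posterior means.
- The semi-parametric retrospective-likelihood and probit-regression
  alternatives are not implemented; comparisons target the logistic family.
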