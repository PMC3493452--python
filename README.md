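# ltcond — informed conditioning on clinical covariates for case-control GWAS

Case-control association studies routinely record clinical covariates — BMI,
age, smoking status — that modify disease risk. Under case-control or
covariate-matched ascertainment, the standard remedies (conditioning on the
covariate in logistic regression, interaction tests, case subsetting) either
lose power or leave the available information on the table. `ltcond`
implements *informed conditioning*: it uses external epidemiological
prevalence data to parameterize a liability threshold (LT) model, converts
each sample's case/control label plus covariates into a posterior mean
residual liability, and tests SNPs against that quantitative pseudo-phenotype.

## The model and the statistic

The liability threshold model posits an unobserved continuous liability

φ = Σ_j c_j (t_j − t̄_j) + m + ε,  ε = γ g_c + N(0, 1),

with an individual affected iff φ ≥ 0. Here t_j are covariates with
liability-scale effects c_j and reference means t̄_j, m fixes the prevalence
at the covariate means (K = Φ̄(−m)), g_c is the mean-centered genotype and γ
the per-allele effect. The package provides:

- **LTPub** (`fit_ltpub`): published prevalences K_i at covariate values t_i
  are mapped to the liability scale, Φ⁻¹(K_i) = c (t_i − t̄) + m, and (c, m)
  solved by closed-form least squares — no search on the disease scale.
- **Posterior mean residual liability** (`posterior_means`): for a case,
  E(ε | z=1, t) = φ(τ)/Φ̄(τ) with τ = −(Σ c_j (t_j − t̄_j) + m); for a
  control, −φ(τ)/Φ(τ). When covariates are measured at disease onset the
  liability sits exactly at the threshold and E(ε | z=1, t) = τ.
- **LT association statistic** (`lt_test`): N·r² between genotype dosage and
  the posterior means — a generalized Armitage trend test, equal to the score
  test of γ at 0, χ²(1) under the null. Nuisance covariates (principal
  components) residualize both sides, generalizing EIGENSTRAT.
- **Comparison statistics** (`baselines`): logistic regression with/without
  covariates, the 2-dof G+GxE joint test, the 1-dof interaction test, subset
  and case-only tests, and an IPW-weighted logistic variant.
- **Simulation engine** (`simulate`, `experiments`): liability and logit
  generators under random, case-control, and case-control-covariate
  ascertainment, with a vectorized replicate engine for power and
  false-positive-rate studies.
- **Analytic power** (`power`): noncentral-χ²(1) power, and the mapping from
  a relative χ² inflation to a power gain.

## Worked example

The matched type 2 diabetes toy design: 3,000 cases and 3,000 BMI-matched
controls, half at BMI 24 and half at BMI 35, causal SNP with population
frequency 0.5 and liability effect γ = 0.1.

```python
import numpy as np
from ltcond import *
from ltcond.io import packaged_prevalence_path, read_prevalence_tables
from ltcond.simulate import toy_t2d_design, run_replicates

# 1. fit the LT model from published prevalence-vs-BMI data
fit = fit_ltpub(read_prevalence_tables(packaged_prevalence_path("t2d_bmi")))
m = fit.model   # c = 0.0806, m = -1.4427 at BMI mean 26.5

# 2. posterior mean residual liabilities for the four design cells
cohort = Cohort(["case_24", "case_35", "ctrl_24", "ctrl_35"], [1, 1, 0, 0],
                ("bmi",), np.array([[24.], [35.], [24.], [35.]]))
pm = posterior_means(m, impute_missing_covariates(cohort))

# 3. replicate study: LT statistic vs logistic regression
design = toy_t2d_design(gamma=0.10, n_replicates=100_000)
summ = run_replicates(design, tests=("lt", "logr"), alphas=(5e-8,), seed=1)
```

Output:

```
fitted model: c = 0.0806, m = -1.4427 (BMI mean 26.5)
case_24: threshold +1.644  posterior mean +2.062
case_35: threshold +0.758  posterior mean +1.335
ctrl_24: threshold +1.644  posterior mean -0.109
ctrl_35: threshold +0.758  posterior mean -0.386
lt    mean chi2 = 31.31 +/- 0.03   power(5e-8) = 0.523
logr  mean chi2 = 29.16 +/- 0.03   power(5e-8) = 0.442
power increase: 18.2%
```

A BMI-24 case has a larger posterior mean (+2.06) than a BMI-35 case (+1.34):
with less help from BMI, more of the liability must have come from genetics,
so low-BMI cases carry more association information. The LT statistic
averages about 2 χ² units above logistic regression in this design and turns
an 18% power gain at the genome-wide threshold P < 5×10⁻⁸. A covariate that
inflates χ² statistics by 16% lifts 43.7% power to
`inflated_power(0.437, 5e-8, 1.16)` → 59.8%.

The same pipeline is scriptable: `ltcond fit`, `ltcond posterior`,
`ltcond assoc` (VCF or dosage-matrix genotypes), `ltcond simulate`,
`ltcond experiment table2|power|null`, and `ltcond power`.

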