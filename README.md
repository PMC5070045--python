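# kinliab

Liability-threshold ACE models for binary traits in sibling and twin pair
data, with a bivariate Cholesky decomposition of cross-trait correlations,
familial-aggregation odds ratios, and polygenic-score prediction — plus
simulators that generate cohorts with known truth for every estimator.

The package targets a recurring design in psychiatric and social
epidemiology: a rare diagnosis (e.g. schizophrenia) and a later
socioeconomic outcome (e.g. residence in a deprived neighborhood, defined
by dichotomizing a continuous deprivation score at an upper percentile) are
both observed on hundreds of thousands of sibling pairs of varying
relatedness, and the question is how much of each trait — and of their
overlap — is attributable to additive genetic (A), shared environmental
(C), and unique environmental (E) influences.  Registry data of this kind
are access-restricted, so the package ships first-class synthetic-data
generators: every analysis can be exercised, and every estimator validated
by parameter recovery, without any external data.

## The model

A binary trait is the indicator that a latent liability `L ~ N(0, 1)`
exceeds a threshold `t = Φ⁻¹(1 − K)` set by the prevalence `K`.  Liability
variance decomposes as `a² + c² + e² = 1`, and the liability correlation of
a pair of type *s* is constrained to

```
r_s = r_A(s)·a² + r_C(s)·c²
```

with `r_A` = 1 (MZ), 0.5 (DZ, full siblings), 0.25 (half siblings) and
`r_C` = 1 for pairs reared together and 0.83 / 0.03 for maternal / paternal
half siblings (census co-residence rates).  Parameters are estimated by
maximum likelihood on the per-stratum 2×2 concordance tables, with one
threshold per pair-type stratum ("relaxed thresholds"), and delta-method
confidence intervals from the observed information.

For two traits, lower-triangular path matrices give `A = a·aᵀ` (likewise C,
E); after standardization the cross-trait tetrachoric correlation is
`r = A₁₂ + C₁₂ + E₁₂`, estimated from the 16-cell tables of the four
dichotomized liabilities per pair and decomposed with confidence intervals
and a Wald test of the unique-environment contribution.

Polygenic scores are `Σ β_j · dosage_ij` over SNPs with discovery
`p ≤ pT`, after effect-allele alignment; their predictive value is the
incremental `R²` over principal-component covariates.

## Worked example

```python
import numpy as np
from kinliab import (GeneratingModel, simulate_univariate_pairs,
                     fit_univariate)

# sibling cohort: heritability 0.65, shared environment 0.03, prevalence 11%
model = GeneratingModel.univariate(a2=0.65, c2=0.03, prevalence=0.11)
cohort = simulate_univariate_pairs(
    model, n_by_pair_type={"FS": 592009, "MHS": 68684, "PHS": 82913}, seed=7)
fit = fit_univariate(cohort.records)
print(f"a2 = {fit.components.a2:.3f}  "
      f"CI ({fit.ci95['a2'][0]:.3f}, {fit.ci95['a2'][1]:.3f})")
print(f"c2 = {fit.components.c2:.3f}  "
      f"CI ({fit.ci95['c2'][0]:.3f}, {fit.ci95['c2'][1]:.3f})")
```

prints (seed 7):

```
a2 = 0.653  CI (0.590, 0.716)
c2 = 0.028  CI (0.000, 0.060)
```

i.e. the fitted additive-genetic share of liability variance is 0.653 with
a 95% delta-method interval of (0.59, 0.72), recovering the generating
value 0.65, and the small shared-environment share 0.03 is likewise
recovered.
The same cohort feeds the descriptive stages (`pair_concordance_summary`,
`proband_relative_or`) and, simulated bivariately, the Cholesky stage
(`fit_bivariate`, `decompose_correlation`).

The command line drives whole studies from YAML:

```
kinliab run-study --config study.yaml --seed 7 --out results/
kinliab sweep --config study.yaml --param relmap.MHS.r_c \
    --values 0.7,0.83,0.95 --seed 7 --out sweep/
```

writing `variance_components.tsv`, `correlation_decomposition.tsv`,
`pair_concordance.tsv`, `odds_ratios.tsv` and a JSON manifest; identical
config + seed reproduces outputs byte for byte.

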