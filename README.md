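# snpsem

Structural equation modelling of multiple SNPs, intermediate phenotypes,
and correlated diseases.

GWAS single-SNP scans report marginal associations and ignore the web of
dependencies between traits. `snpsem` implements a four-step procedure
that turns a genotype–phenotype cohort into a *quantitative map*: directed,
standardized paths running from SNPs, through latent genetic factors and
intermediate phenotypes, to one or more correlated diseases. The worked
application is the adiposity–metabolic-disease system: three obesity
phenotypes — subscapular skin fold thickness (SUB, subcutaneous
adiposity), body mass index (BMI, overall adiposity), and waist
circumference (WC, abdominal adiposity) — mediating genetic effects on
type 2 diabetes (T2D) and hypertension (HTN), in the clinically ordered
cascade SUB → BMI → WC → T2D → HTN.

The four steps:

1. **Association scan** (`SingleSNPScan`): per-SNP linear (continuous
   traits) or logistic (diseases) regression with demographic covariates;
   SNPs with p < 1×10⁻⁵ form a per-trait *SNP block*.
2. **Latent factors** (`SNPFactorModel`): per-block exploratory factor
   analysis — principal-component extraction of the dosage correlation
   matrix, Kaiser retention (eigenvalue > 1), varimax rotation, iterative
   exclusion of SNPs with communality < 0.3 — and standardized
   per-subject factor scores.
3. **Phenotype network** (`partial_correlation`, `PathModel`):
   covariate-adjusted partial correlations among phenotypes and diseases,
   then a recursive path analysis over the mediation ordering.
4. **Structural equation model** (`SEModel`): maximum-likelihood
   covariance-structure estimation in RAM form,
   Σ(θ) = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ, minimising
   F_ML = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p,
   with fit indices (χ², NFI, CFI, GFI, AGFI, RMSEA against the cutoffs
   NFI ≥ .95, CFI ≥ .95, GFI ≥ .95, AGFI ≥ .90, RMSEA ≤ .07) and the
   standardized effect decomposition
   **direct** = B, **total** = (I−B)⁻¹ − I, **indirect** = total − direct,
   with delta-method standard errors and an optional case-resampling
   bootstrap for indirect effects.

A synthetic-cohort generator (`SimConfig`, `generate_cohort`) produces
KARE-like cohorts — HWE genotypes in correlated clusters, a latent factor
per cluster, the standardized trait cascade, and liability-threshold
diseases calibrated to 9.45 % (T2D) and 27.06 % (HTN) prevalence — so
every stage is testable without access to restricted cohort data.

## Worked example

The published covariate-adjusted partial-correlation matrix of the KARE
cohort (n = 8,792) ships with the package, so step 3–4 run without any
genotype data:

```python
import snpsem as ss

R = ss.kare_phenotype_correlations()          # 5x5: SUB, BMI, WC, T2D, HTN
spec = ss.default_disease_paths()             # SUB->BMI->WC->T2D->HTN, 10 edges
fit = ss.SEModel(spec.to_sem_spec(), cov=R, n=ss.KARE_N).fit()

print(fit.standardized_path("BMI", "WC"))     # 0.7979379...
print(fit.effect("SUB", "WC", "direct"))      # 0.0411070...
print(fit.effect("SUB", "WC", "indirect"))    # 0.5058926...
print(fit.effect("SUB", "T2D", "total"))      # 0.1209999...
```

Overall adiposity carries almost the whole association between
subcutaneous and abdominal adiposity (0.041 direct vs 0.506 mediated),
and subcutaneous adiposity retains a total standardized effect of 0.121
on T2D once its mediated pathways are summed — the mediation story the
quantitative map is built to expose.

The same model from the shell, plus a fully synthetic end-to-end run:

```sh
snpsem simulate --n 5000 --seed 7 --out sim/
snpsem scan --genotypes sim/genotypes.csv --phenotypes sim/phenotypes.csv
snpsem pathfit --corr corr.csv --n 8792
snpsem run --config pipeline.yaml
```

`snpsem run` executes all four steps from one YAML config and writes
`scan.tsv`, `blocks.json`, `loadings.tsv`, `factor_scores.csv`,
`partial_correlations.csv`, `path_fit.tsv`, `sem_fit.json`,
`effects.tsv`, and DOT diagrams (dashed edges mark p ≥ 0.05) under the
output directory, with a `report.json` index.

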