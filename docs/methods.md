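# Methods

## The model

`snpsem` analyses an n×c cohort matrix A = [X | Y | Z]: a genotype block
X (additive 0/1/2 dosages), intermediate phenotypes Y (SUB, BMI, WC on
the adiposity application), and binary diseases Z (T2D, hypertension),
with demographic covariates (sex, area, age) carried alongside. The
analysis has four stages, each usable on its own.

**Stage 1 — single-SNP screening.** Each SNP is tested against each
trait by linear regression (continuous) or logistic regression (binary),
always with covariates, reporting per-allele Wald statistics. The linear
scan residualizes the trait and all dosage columns on the covariate
design once (QR), then computes per-SNP slopes; by the
Frisch–Waugh–Lovell theorem the estimates, SEs and p-values are
algebraically identical to the full per-SNP OLS fit (verified against
statsmodels in the tests). Logistic fits use IRLS to a 1e-8 step
tolerance, at most 50 iterations; non-convergence (e.g. separation) and
monomorphic SNPs are flagged and never enter blocks. The block threshold
defaults to p < 1×10⁻⁵, applied per trait with no multiplicity
correction; optional greedy LD pruning (keep a SNP iff r² with every
kept SNP is below threshold, in p-value order) is off by default.

**Stage 2 — latent factors per block.** For each SNP block the dosage
Pearson correlation matrix R is eigendecomposed and loading column j is
√λ_j·v_j (principal-component extraction). The factor count defaults to
the Kaiser rule (eigenvalues strictly > 1), overridable per block; a
one-SNP block is its own factor with loading exactly 1. Extraction is
followed by varimax rotation (Kaiser-normalized pairwise rotations,
criterion change < 1e-9), which preserves row communalities and total
variance explained. SNPs with communality below 0.3 are dropped one at a
time (lowest first) with full re-extraction until all retained
communalities pass — a single exclusion pass generalized to an iteration
so the result does not depend on exclusion order. Factor scores are
standardized rotated principal-component scores, Z V Λ^(−1/2) T: exactly
mean 0, variance 1, and mutually orthogonal in sample. Extraction and
score methods are deliberate design choices among the unreported
conventions of legacy statistical packages; principal-component
extraction matches the near-unity loadings such packages produce on
tightly linked SNPs. Eigenvector signs are fixed so each column's
largest-magnitude entry is positive, making the whole stage
deterministic; loading ties in factor assignment go to the lower-indexed
factor and are logged.

**Stage 3 — phenotype network.** Partial correlations are computed by
the residual method (correlate least-squares residuals after regressing
every variable on the covariates; t reference with n − #covariates − 2
df), which the tests verify against both the closed-form recursion on
marginal correlations and pingouin. The mediation ordering
SUB → BMI → WC → T2D → HTN is an *input*, grounded in the clinical
argument that abdominal adiposity is the proximal obesity measure for
insulin resistance and that T2D raises hypertension risk; no causal
search is performed. The recursive path model is fitted by standardized
least squares on the correlation matrix (normal equations per
endogenous variable), which is exactly the ML solution for a recursive
system with free residuals and is identical between raw-data and
matrix-mode input.

**Stage 4 — structural equation model.** The SEM is held in RAM form
(directed-path matrix A over observed and latent variables, symmetric S
of exogenous variances/covariances and residuals, selection matrix F)
and estimated by minimising the ML discrepancy
F_ML = ln|Σ(θ)| + tr(SΣ(θ)⁻¹) − ln|S| − p with BFGS from per-equation
OLS starting values (gradient tolerance 1e-8, up to 5 jittered
restarts). χ² = (n−1)·F_ML (Wishart convention), df = p(p+1)/2 − #free.
Standard errors come from the inverse expected information,
I_ij = (n−1)/2 · tr(Σ⁻¹∂Σ_i Σ⁻¹∂Σ_j). When the model attaches no fixed
constants to observed variables it is scale-invariant, and the
optimisation internally runs on the correlation rescaling of the sample
matrix and maps the optimum back — this is exact, and it is what makes
fits stable when binary 0/1 diseases (variance ≈ 0.07–0.2) sit next to
unit-variance factor scores. Binary endogenous variables are analysed
as numeric 0/1 under normal-theory ML — a deliberate replication of the
legacy estimator and a documented limitation (coefficients into binary
outcomes are attenuated relative to the liability scale; no
polychoric/DWLS correction is applied). Latent variables are
scale-identified by fixing their variance to 1 unless a loading is
fixed. Residual covariances (correlated measurement errors, e.g. the
same SNP serving as an indicator in two blocks) are user-specified
pairs; no modification-index search is automated.

Fit indices: NFI = (χ²_b − χ²_m)/χ²_b; CFI = 1 − max(χ²_m − df_m, 0) /
max(χ²_b − df_b, χ²_m − df_m, 0); GFI = 1 − tr[(Σ̂⁻¹S − I)²]/tr[(Σ̂⁻¹S)²];
AGFI = 1 − [p(p+1)/(2df)](1 − GFI); RMSEA = √(max(χ² − df, 0)/(df(n−1))).
The independence baseline has the closed form χ²_b = (n−1)(Σln s_ii −
ln|S|) on p(p−1)/2 df. For saturated models AGFI and RMSEA are reported
as undefined-by-saturation (`None`), never NaN, and count as passing the
cutoff battery.

Effects: with the standardized path matrix B (post-fit rescaling by
implied standard deviations), direct = B, total = (I−B)⁻¹ − I,
indirect = total − direct; the identity total = direct + indirect holds
to machine precision by construction and is asserted to 1e-10 in the
tests. Standard errors are delta-method (numerical Jacobian of the
standardized effects against the parameter covariance); stars follow
* p<.10, ** p<.05, *** p<.01. `bootstrap_indirect` offers nonparametric
case-resampling percentile intervals (raw-data mode only, B ≥ 200,
seed-reproducible) as the distribution-free alternative for indirect
effects; product-distribution methods are out of scope.

## The synthetic generator

`generate_cohort` emulates the statistical structure the analysis
assumes, not any particular chromosome. Genotypes: per cluster, an
equicorrelated Gaussian copula is thresholded at the HWE cumulative
probabilities (1−p)², 2p(1−p) of each SNP's MAF, giving exact HWE
margins and within-cluster dosage correlation somewhat below the latent
r (discretization attenuation; tests bound it empirically). One latent
factor per cluster is the in-sample standardized mean of the cluster's
standardized dosages. Traits and disease liabilities form a linear
recursive system over a mutually independent unit-variance basis
(factors, population-standardized covariates, equation residuals);
each equation's residual variance is solved so the total variance is
exactly 1, and a configuration whose systematic variance reaches 1 is
rejected with the offending equation named. Diseases are indicators of
liability > Φ⁻¹(1 − prevalence), so population prevalence is matched
exactly; the T2D → hypertension coefficient acts on the T2D *liability*,
keeping the joint system Gaussian and the thresholds exact (the
alternative — a coefficient on the 0/1 indicator — would make unit
variances and thresholds only approximate).

Defaults are the study-scale conditions: n = 8,842; prevalences 9.45 %
(T2D) and 27.06 % (hypertension); sex and area Bernoulli at the
cohort's published proportions; age uniform on [39, 70] (only
mean/SD/range are published; uniform is the least-committal choice on
the range); five SNP clusters sized (5, 7, 7, 1, 4); cascade
coefficients at the published standardized estimates. Covariate effect
sizes are not public; the defaults are small non-zero values chosen
once so covariate adjustment is genuinely exercised, and are documented
as arbitrary. The generator does **not** simulate blood-pressure or
glucose component measurements, medication, realistic LD maps,
population structure, or missingness — so passing tests demonstrate
estimator correctness under the assumed structure, not robustness to
those real-data features.

## Test and acceptance problem sizes

Module examples run at desk scale by design: HWE/χ² checks on 100 SNPs
at n = 5,000; null-scan uniformity on 200-SNP scans at n = 500;
bootstrap coverage at 20 seeds × B = 200 × n = 600; χ² calibration over
500 replicates of a 1-df chain at n = 200; planted-structure recovery
over 100 seeds at n = 5,000. The SEM parameter-recovery battery refits
the generating structure on 100 cohorts of n = 20,000 and requires every
continuous structural coefficient inside ±0.02. That band is only
meaningful where the sampling SD makes it a ≥3σ event: with the
published cascade values the implied BMI–WC collinearity (r ≈ 0.82)
pushes the asymptotic SE of the disease-equation coefficients to
≈0.013, i.e. the band would be a ~1.5σ event per seed for *any* correct
estimator. The recovery battery therefore uses a balanced strong-effect
configuration selected by an a-priori power calculation (worst-case
band ≥ 3.4 asymptotic SDs), while the published values remain the
generator defaults everywhere else. Recovery of disease-equation
coefficients is assessed against the generator's latent liabilities
(recorded in the truth record): on the 0/1 indicators, normal-theory ML
is attenuated by construction and exact recovery is not a property the
estimator claims.

## Known limitations

- Normal-theory ML on binary endogenous variables (attenuation; SEs
  approximate). This replicates the legacy estimator deliberately.
- Partial correlations treat 0/1 diseases as numeric; no biserial or
  polychoric option.
- The mediation ordering is assumed, not discovered; alternative
  orderings fit equally well at the saturated phenotype level.
- The Kaiser rule can grant an isolated noise SNP its own factor
  (eigenvalue fluctuates around 1); the per-block factor-count override
  exists for exactly this case, and the communality filter then removes
  the SNP.
- Matrix-mode input cannot support the case-resampling bootstrap.
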