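# Methods

This note documents the statistical models, numerical choices and known
limitations of `gremlite`. It is written for users who want to know
exactly what the package computes and what the test suite does and does
not demonstrate.

## Models

**Univariate GREML.** The response for each trait is the vector of sex-
and age-adjusted z-scores. The mixed model is y = Xβ + u + e with
Var(u) = Gσ²u and Var(e) = Iσ²e; G is the genomic relationship matrix
built from standardized allele counts,

f_jk = (1/N_jk) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2p_i(1 − p_i)),

with p_i the sample frequency of the counted allele and N_jk the per-pair
count of SNPs non-missing in both individuals. Missing genotypes
contribute nothing to either the numerator or N_jk (no mean imputation);
this matches the per-pair-count companion file of the binary GRM format.
SNP heritability is h² = σ²u/(σ²u + σ²e).

**Bivariate GREML.** Two traits are stacked; the random effects have
covariance [g_ij] ⊗ G and the residuals [r_ij], where r12 applies only to
individuals observed for both traits. The genetic correlation is
rg = g12/√(g11 g22), with a delta-method SE from the 6×6 inverse
average-information matrix. When the two traits share an identical sample
and design, a single eigendecomposition of G makes each REML iteration
O(n p²) (the rotated covariance is 2×2-block-diagonal per
eigencomponent); otherwise a dense-matrix path handles arbitrary
overlapping samples. With zero overlap r12 is unidentifiable and is fixed
at 0 with a warning.

**Restricted likelihood and optimizer.** The REML log-likelihood is
−½[log|V| + log|XᵀV⁻¹X| + yᵀPy] (constants dropped; the same convention
is used for the σ²u = 0 null, so likelihood-ratio statistics are exact).
AI-REML iterates θ ← θ + AI⁻¹s with s_i = −½[tr(PA_i) − yᵀPA_iPy] and
AI_ij = ½yᵀPA_iPA_jPy. Numerical safeguards, in order:

- the first univariate step is EM-REML (AI steps can overshoot from
  crude starting values);
- any step that would decrease the likelihood is halved (accepted
  iterations are monotone; the test suite asserts this on the trace);
- variance components are clamped at 1e-6 × the phenotypic variance;
  a component sitting at that floor with an outward-pointing score is
  frozen out of the update (active-set treatment of the boundary), which
  is what makes null-trait fits land exactly on the σ²u = 0 profile;
- if the AI direction fails or the AI matrix is ill-conditioned, the
  univariate fitter falls back to an EM step and the bivariate fitter to
  Levenberg–Marquardt damping (AI + λ·diag, λ escalating), which keeps
  progress along near-singular ridges such as rg → 1 when the two traits
  are nearly identical;
- an AI matrix that is singular at the very first usable step signals a
  structurally unidentifiable model (e.g. G = I) and raises an error.

Convergence requires |Δ log-likelihood| < 1e-4 and a max-norm parameter
change < 1e-4 (relative to the phenotypic variance) on a full, unhalved
step; the default iteration cap is 100. Estimate covariances are AI⁻¹ at
the optimum; h² and rg SEs use the delta method. Heritability p-values
use the boundary mixture ½χ²₀ + ½χ²₁ applied to the REML LRT against the
σ²u = 0 null (the component lies on the parameter-space boundary under
the null). A Wald alternative would be anticonservative near the
boundary; the mixture LRT calibrates well in the null simulations.

As an independent check, `profile_h2_argmax` maximizes the same
restricted likelihood by a completely different route: the total variance
profiles out in closed form (V̂tot = yᵀP_My/(n−p) for V = Vtot·M(h²)),
leaving a 1-D profile in h² that is scanned on a grid and refined by
bounded scalar minimization. The acceptance suite requires AI-REML and
the grid argmax to agree to |Δh²| < 1e-3 on thirty simulated instances.

## Quality control

The filter chain runs: individual call rate ≥ 0.98 → SNP call rate ≥
0.98 (computed on surviving individuals) → MAF ≥ 0.01 → HWE exact p ≥
1e-6 → LD pruning (window 50, step 5, r² > 0.2) → heterozygosity
outliers (±3 SD of the het rate on the pruned set) → IBD relatedness
removal (pi-hat > 0.2, keep the higher-call-rate member, ties drop the
later-listed one) → a final looser pruning pass (r² > 0.7) defining the
analysis SNP set. Each stage logs in/removed/out counts and the counts
telescope. Sample allele frequencies are re-estimated after each
individual-removal stage because downstream statistics recompute them
from the surviving data.

The HWE test is the exact conditional test: given the allele counts, the
p-value sums the probabilities of all heterozygote counts whose
conditional probability does not exceed the observed one (no mid-p
correction — the conventional default of standard QC tools). It is
validated exhaustively against an independent integer-arithmetic
enumeration for every genotype configuration up to n = 50.

LD pruning is greedy within windows: while any retained pair in the
window exceeds r², the member with the lower MAF is dropped (tie: later
map position) and the window slides by the step. The pair-scan order is
lexicographic, which makes the output deterministic; the acceptance suite
pins it against a naive O(m²)-per-window reference pruner.

IBD uses plain method-of-moments estimation from identity-by-state counts
and sample allele frequencies, with negative probabilities clamped to
zero and the triple renormalized. No small-sample frequency corrections
are applied; with a few thousand pruned SNPs and cohort-scale n the bias
is well below the 0.2 pi-hat threshold (duplicates score ≈ 1.0,
parent-offspring ≈ 0.5 ± 0.02 in the tests). All O(n²) pairs are
evaluated exactly — no windowed approximation — which is acceptable at
the sample sizes the package targets.

Heterozygosity outliers are computed on the r² 0.2-pruned SNP set; the
convention on which SNP set backs this statistic varies between
pipelines, and the pruned set was chosen because it is the set on which
the other per-individual statistic (IBD) is computed.

## Phenotype handling

Participants with BMI < 16 kg/m² (the WHO severe-thinness line) are
dropped from the whole table; afterwards, per trait and per sex group,
values beyond ±6 SD are set to missing for that trait only. The order
matters and is fixed: the SD statistics are computed after the BMI-floor
removal, once, not iteratively (iterating would shrink n unpredictably).
Blanking the single cell rather than the participant preserves the
per-trait sample sizes that differ naturally across traits. Note a ±k SD
rule can never fire in tiny groups — the outlier inflates the SD it is
judged against (max attainable z in a group of size g is (g−1)/√g) — so
it is only meaningful at cohort scale.

Adjustment regresses each trait on age by OLS within each sex group and
standardizes the residuals to z-scores (n−1 denominator). Sex comes from
the sample metadata, not genotype inference. Groups with zero age
variance fall back to centering with a warning.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes,
with truth records for every stage:

- **Genotypes.** Ancestral frequencies uniform on a configurable MAF
  range (default 0.05–0.5); under structure, subpopulation frequencies
  follow the Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) model; LD is a
  first-order allele-copy chain on haplotypes (copy probability ρ gives
  adjacent dosage correlation ≈ ρ at equal frequencies); related pairs
  (duplicate / parent-offspring / full-sib) are constructed by explicit
  per-SNP gamete transmission, so their expected pi-hat values are the
  pedigree ones.
- **Phenotypes.** One causal SNP set shared across traits; effect
  vectors drawn with across-trait covariance R_g on standardized
  dosages; residuals with covariance R_e. Both the genetic scores and
  the residuals are rescaled by their realized standard deviations so
  that the realized Var(g) = h² and Var(e) = 1 − h² exactly — this
  removes one layer of Monte-Carlo noise and tightens desk-scale
  parameter-recovery tests (the realized h² of the sum still differs
  from the target by the sampling covariance between g and e). Sex
  effects, per-sex age slopes and batch (platform/prefecture) shifts
  enter the mean. Ages are uniform within sex-specific adult ranges and
  the default sex ratio is 1:2 male:female, mimicking typical
  community-cohort composition, so the sex-stratified adjustment is
  exercised realistically.

What the simulator does **not** emulate: realistic human LD maps (the
chain has geometric decay only), selection, dominance or epistasis,
assortative mating, imputation uncertainty, and non-Gaussian trait
distributions. Passing recovery tests therefore demonstrates correctness
of the estimation machinery under the model's own assumptions, not
robustness to the ways real cohort data violate them.

## Reference correlation table

`gremlite/data/cohort_correlations_17traits.tsv` packages published
large-cohort estimates for 17 obesity-related traits in Japanese adults:
136 genetic correlations (bivariate GREML, with SEs and significance
marks) and 136 phenotypic correlations (Pearson on adjusted z-scores).
It backs the concordance analysis — Pearson(rp, rg) over all pairs, and
the maximum |rg − rp| after excluding the three low-heritability urinary
biomarkers (uCre, uCl, uK), whose rg estimates carry large SEs. The
Pearson statistic deliberately uses *all* pairs while only the
max-discrepancy honors the exclusion set; values are as printed (3
decimals), which is why the concordance checks carry a ±0.02 tolerance.

## Problem sizes used in tests

Unit tests run on cohorts of 60–1500 individuals. The statistical
acceptance suite uses: 30 instances of n=300/m=500 for the
optimizer-oracle check; 20 replicates of n=2000/m=2000 for univariate
recovery at h²=0.5 (mean estimate within 2 empirical SEs; mean
delta-method SE within 30% of the empirical SD); 20 replicates of n=2000
for bivariate recovery at rg=0.8; and 200 replicates of n=500 for null
calibration (empirical rejection rate at the 5% level inside the exact
binomial band). These sizes give the recovery tests useful power while
keeping the whole suite at a few minutes on one CPU; `scripts/
acceptance.py` uses slightly smaller replicate sizes for the same
quantities.

## Known limitations

- Single-component GREML only: no partitioned GRMs,
  leave-one-chromosome-out, dominance components or GxE.
- Variance components are boundary-constrained; no unconstrained
  (negative-variance) mode, so h² and rg estimates are biased slightly
  inward at the boundaries relative to unconstrained REML.
- The bivariate dense path materializes (n1+n2)² matrices; it is meant
  for moderately sized non-identical samples. The fast path requires
  identical samples and designs.
- Autosomes only; no chromosome X dosage compensation handling.
- The PLINK reader supports the SNP-major v1.00 binary layout only and
  rejects individual-major files explicitly.
- PCA eigendecomposes the GRM; this equals genotype-matrix PCA up to
  scaling under the standardization used here.
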