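# Methods

## The liability-threshold model and scale transformation

A binary disease status y ∈ {0,1} is modelled as an underlying liability
ℓ = g + e, g the additive genetic effect (Var(g) = σ²_u, pedigree
covariance A σ²_u), e ~ N(0,1). An animal is affected when ℓ exceeds the
threshold z = Φ⁻¹(1−α) for prevalence α. Heritability on the liability
scale is h²_u = σ²_u/(σ²_u+1); on the observed 0/1 scale it is

h²_o = h²_u · w²/(α(1−α)), w = φ(z) = e^(−z²/2)/√(2π).

The factor w²/(α(1−α)) is symmetric in α ↔ 1−α and maximised at α = 0.5,
where it equals 2/π; both directions of the transformation are exposed and
compose to identity to machine precision. The sign of z is immaterial
(only z² enters); we take z = Φ⁻¹(1−α).

## PQL probit animal model

`estimate_h2_pql_probit` is penalised quasi-likelihood with a probit link:
iterate (i) working response t_i = η_i + (y_i − Φ(η_i))/φ(η_i) and weights
w_i = φ(η_i)²/(Φ(η_i)(1−Φ(η_i))); (ii) REML of the working linear mixed
model t = 1μ + Zu + ε, u ~ (0, A σ²_u), ε ~ (0, W⁻¹), by 1-d profile
likelihood over σ²_u on Henderson's mixed-model equations (sparse A⁻¹ from
Henderson's rules with Meuwissen–Luo inbreeding; log|A| = Σ log d_i);
(iii) η ← μ̂ + û; until |Δσ²_u| < tol (default 1e−6, max 200 iterations,
σ²_u searched in [1e−6, 50]). Residual liability variance is fixed at 1
(probit identification), so h²_u = σ²_u/(σ²_u+1). The SE comes from the
numerical curvature of the profile REML log-likelihood with a delta-method
conversion to the h² scale. Either a `Pedigree` (preferred — the sparse
route handles thousands of animals in seconds) or a dense
`AdditiveRelationship` may be supplied; repeated records for one animal
share a single genetic effect.

**Attenuation (known limitation).** For binary data with a *per-animal*
random effect, the PQL working model posits individual-level genetic
variance that 0/1 observations cannot express; the genetic signal survives
only in between-relative covariances. The estimator therefore attenuates
substantially: on cohorts of 2000 offspring in 100 paternal half-sib
families with true h²_u = 0.4 and prevalence 0.5, the PQL estimate centres
near 0.17 (we verified the implementation against an independent PQL
implementation on a shared random-intercept model; the two agree to three
decimals, so this is the method, not the code). This is the
Breslow–Lin-type bias, worst at effective cluster size one. For unbiased
liability-scale estimation the package provides
`estimate_h2_observed_reml`: linear animal-model REML applied directly to
the 0/1 records followed by the observed→underlying transformation at the
sample prevalence. On the same design it centres near 0.42. The pipeline
reports both.

## GQLS association test

Per SNP, the allelic proportion Y_i = dosage/2 ∈ {0, ½, 1} is the
response, status X_i ∈ {0,1} the covariate, with logistic mean
μ = e^(β₀+β₁X)/(1+e^(β₀+β₁X)) and quasi-score test of H₀: β₁ = 0. The
concrete statistic (fixed convention): working covariance V = v(μ̂₀)·K
with variance function v(μ) = μ(1−μ)/2 (binomial variance of a two-allele
count, on the proportion scale) and K the additive relationship matrix of
the tested animals; μ̂₀ = (1ᵀK⁻¹y)/(1ᵀK⁻¹1);
U = xᵀK⁻¹(y − μ̂₀1); Var(U) = v(μ̂₀)[xᵀK⁻¹x − (xᵀK⁻¹1)²/(1ᵀK⁻¹1)];
T = U²/Var(U) ~ χ²₁. With K = I this is the classical score test for the
logistic-type mean model; T is invariant to which allele is counted. No
overdispersion parameter is estimated by default; `estimate_dispersion`
adds a moment estimator dividing T. Missing genotypes are handled per SNP,
pairwise complete: the genome scan factorises K once (Cholesky) and reuses
the solves for all complete SNPs, re-factorising the sub-matrix only for
SNPs with missing calls. Monomorphic SNPs are flagged and given p = 1.

## Chromosome-wise positive FDR

Storey q-values computed independently per chromosome:
π̂₀(λ) = #{p > λ}/(m(1−λ)) over λ = 0.05,…,0.95, cubic-polynomial smoother
evaluated at λ = 0.95, clipped to (1/m, 1]; chromosomes with < 100 SNPs
fall back to π̂₀ = 1 (the Benjamini–Hochberg limit — with π̂₀ = 1 the
q-values coincide with BH step-up values exactly). q_(i) = min_{j≥i}
π̂₀·m·p_(j)/j. Tiers assign each SNP the smallest cutoff in
{0.01, 0.05, 0.10} with q ≤ cutoff. Manhattan export truncates −log₁₀(q)
at 6 and flags exceedances so plots can mark them.

## Post-GWAS filter cascade

Inputs are the SNPs significant at pFDR ≤ 10%. Stages, cumulative and in
fixed order: (1) MAF ≥ 0.2 over non-missing calls; (2) Pearson chi-square
of the 2 (status) × k (observed genotype classes) table, no continuity
correction, df = k−1, absent classes dropped, small expected counts warn
rather than fail; (3) homozygotic polarity score ≥ 0.3, where within each
phenotype class the proportions of the two homozygotes (denominator = all
non-missing animals of the class) are differenced and the absolute
between-class difference of these differences is the score ∈ [0,2]. If one
homozygote class is absent in the entire cohort the score is N/A; N/A
never passes but the SNP is retained in the report. Per-stage survivor
counts are reported overall and per chromosome.

## Random-forest consensus

Classification forests on dosage features (missing calls mean-imputed per
SNP), inverse-class-frequency sample weights so the prediction error is
weighted evenly between disease statuses, √m features per split, 75 trees
per forest and 100 replicate forests by default (tests and the demo use a
scaled 20–25-tree/3–20-forest protocol; the full protocol is a config
value). VIM% is Breiman permutation importance on each tree's out-of-bag
samples — mean decrease in accuracy × 100, averaged over trees. Only
features a tree actually splits on can change its predictions under
permutation, so per-tree importance is computed over the tree's split
features (exact, and what makes genome-sized scans cheap). Negative
importances are recorded but count as zero for the "non-zero VIM%"
retention rule. Consensus: SNPs with positive VIM% in ≥ 2 forests; forest
frequency (count of such forests) is the primary ranking, ties included
when flagging the top half as genomic areas of interest. OOB (estimation)
error and held-out (prediction) error are reported overall and per class.
A regression-on-0/1 mode exists behind a flag for comparability
experiments. Replication is sequential with per-forest seeds
base_seed + k, so results are bitwise reproducible.

## LD, haplotype blocks, gene mapping

Two-locus haplotype frequencies from unphased genotype pairs by EM (the
double heterozygote is the only ambiguous class; tolerance 1e−10 on the
log-likelihood, max 1000 iterations, monotonicity asserted);
r² = D²/(p_A(1−p_A)p_B(1−p_B)), D′ = |D|/D_max. Per-pair error against
phased-truth counting is dominated by the realized phase split of double
heterozygotes and is heavy-tailed across random pairs; at n = 200 the
median error is ~0.01 while individual pairs can deviate by ~0.05, so
validation compares the median over seeded pairs.

Solid-spine blocks: a block [i..j] is valid when the first and the last
marker are each in strong LD with every interior marker and with each
other (r² ≥ 0.2 by default; D′ ≥ 0.8 available via `statistic="dprime"`).
Scanning left to right, each start takes the largest valid end; blocks
span ≥ 2 SNPs and never cross a chromosome boundary.

Gene mapping: a SNP maps to every gene whose body overlaps
[pos − 2 Mb, pos + 2 Mb] (1-based inclusive; BED input converted from
0-based half-open; GFF3 native). Distance is 0 inside the gene, else the
signed gap to the nearer gene boundary. The syntenic screen keeps
(significant SNP, within-gene SNP) pairs with r² ≥ 0.2 on the same
chromosome regardless of distance; cross-chromosome requests are errors.
LD is computed on whatever cohort is supplied — pass a larger reference
panel when one is available, since small case-control cohorts estimate r²
noisily.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
the scale the defaults state: 29 autosomes with 1443 evenly spaced
biallelic markers each (≈ 50K-chip density), founder allele frequencies
uniform on (0.05, 0.5], a multi-generation pedigree in which each
generation's dams are mated to a handful of sires (large paternal half-sib
families, as under artificial insemination), gene dropping with one
uniformly placed crossover per chromosome per meiosis (count
configurable), and completely-at-random missingness. The liability is
Σ β_k g_k + u + e with 5 QTL of N(0, 0.35²) effects, the polygenic u
simulated by the pedigree cascade (founders N(0, σ²_u); offspring
½(u_s+u_d) plus a Mendelian-sampling deviate scaled by parental
inbreeding — exactly consistent with the A matrix used downstream), σ²_u
chosen so total genetic variance matches h²_u = 0.41 on the unit-residual
scale, and e ~ N(0,1). Status is assigned by thresholding at the realized
(1 − prevalence) liability quantile, which pins the case count (157/265 at
the default prevalence 0.5925) up to integer rounding — chosen over the
theoretical Φ⁻¹ threshold because downstream tests need controlled case
counts. 265 phenotyped animals are drawn from the final generation and
split 40/225 into training/testing.

Not emulated: real linkage-map heterogeneity, mutation, selection,
genotyping error, sex chromosomes, and any particular QTL architecture of
a real trait (the architecture here is a labelled stand-in). Passing tests
therefore demonstrate correctness of the pipeline's statistics under the
threshold model, not biological claims about any real disorder.

## Numerical and design choices

- "Heterozygosity excess" in QC = observed het frequency − Hardy–Weinberg
  expectation on non-missing calls, excluded at ≥ 0.499; the MAF screen
  excludes MAF ≤ 1e−5 (drops monomorphic and near-monomorphic markers
  only). Filter order is fixed: animals by call rate, SNPs by call rate,
  het excess, MAF; each removal attributed to exactly one filter, so QC is
  idempotent and the report reconciles with matrix shapes.
- PLINK text dialect: counted allele = second distinct allele observed in
  file order ("0 0" = missing); the writer emits heterozygotes as "a b" so
  round trips are stable whenever a non-B-homozygote precedes the first
  B/B animal. MAF and every downstream statistic are allele-symmetric.
- Unknown pedigree parents contribute zero relationship (no unknown-parent
  groups); a single known parent is treated as (known, unknown) in A but
  rejected by the simulator's gene dropper (which needs both gametes).
- Sparse MME factorisations use LU without row pivoting in symmetric mode;
  the matrices are positive definite so |C| is recovered from the U
  diagonal.
- The kinship handed to the association scan is the pedigree A-submatrix
  of the tested animals; a genomic relationship matrix can be substituted
  wherever an `AdditiveRelationship` is accepted.
- Empty chromosomes, empty SNP sets after QC, and empty significant sets
  are no-ops with warnings, not errors; single-phenotype-class cohorts are
  errors everywhere.

## Problem sizes used in validation

Tests run desk-scale versions of every stochastic check: type-I error on
2000 null SNPs at n = 200; heritability recovery on 20 replicates of the
2000-animal half-sib design; forest consensus at 20 forests × 25 trees
over 1000 SNPs (100 single-forest seeds for the detection check); LD
validation on 40 seeded pairs at n = 200; and a 5-chromosome × 400-SNP
demo pipeline, re-run to confirm byte-identical outputs. The full
100 × 75 forest protocol and study-scale marker density remain the
library defaults.
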