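# Methods

`singlestep` implements a complete genetic evaluation and association
pipeline for lowly heritable, repeated-record livestock traits (the
motivating case is litter size in a closed pig herd): pedigree and genomic
relationship matrices, variance-component estimation, breeding-value
prediction, and a weighted single-step GWAS with sliding-window variance
scans. This note records the models, the numerical choices, and what the
synthetic data generator does and does not emulate.

## The repeatability animal model

All evaluation rests on the single-trait linear mixed model

    y = Xb + Za + Wpe + e

with fixed effects `b` (intercept, parity, year-season), additive genetic
effects `a` with Var(a) = K σ²ₐ, a permanent-environment effect per recorded
animal with Var(pe) = I σ²ₚₑ, and iid residuals. The relationship structure
K is the pedigree numerator matrix A (pedigree BLUP), or the combined
single-step matrix H whose inverse is

    H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹]

on the genotyped block. Heritability is h² = σ²ₐ / (σ²ₐ + σ²ₚₑ + σ²ₑ).

**A and A⁻¹.** A is built by the tabular method; its sparse inverse by
Henderson's rules using Mendelian-sampling variances computed from
inbreeding coefficients (Meuwissen–Luo recursion). Inbreeding is included
by default — the conservative, more general choice — with a flag to assume
F = 0. Unknown parents are the sentinel "0"; unknown-parent groups are not
modelled.

**G.** The genomic matrix is the allele-frequency-scaled cross-product
G = Z D Z′ / Σ 2pᵢ(1−pᵢ) with Z the column-centered gene content, pᵢ the
counted-allele frequency computed from the genotyped samples, and D the
diagonal SNP-weight matrix (D = I for plain single-step). Because
2pᵢ(1−pᵢ) is symmetric in allele labelling, the scaling is orientation-
invariant. Residual missing genotypes are mean-imputed (2pᵢ) after QC.
With same-sample frequencies, Z is exactly column-centered, so G is always
singular along the all-ones vector; we therefore blend G* = τG + (1−τ)A22
with τ = 0.95 (a common single-step default) before inversion. No
additional tuning of G to the A22 scale is applied by default.

## AI-REML

Variance components are estimated by average-information REML. Each round
computes, from one factorization of the mixed-model equations:

- the EM updates (guaranteed never to decrease the restricted likelihood),
- the gradient of the restricted log-likelihood via the trace identities
  tr(P ZKZ′) = q/σ²ₐ − σ²ₑ tr(K⁻¹C_aa)/σ⁴ₐ etc., and
- the average-information matrix from three extra solves against the
  factor (working vectors Zâ/σ²ₐ, Wp̂e/σ²ₚₑ, ê/σ²ₑ).

The AI (Newton-type) step is taken when it stays inside the parameter
space; otherwise the round falls back to EM, and an AI step that lowered
the likelihood is rewound. Convergence is a maximum relative component
change below 1e−8 within 200 rounds. Components are floored at 1e−10 of
the phenotypic variance. Standard errors come from the inverse AI matrix;
the h² standard error uses the delta method. A near-singular AI matrix
(condition number above 1e10) flags a flat likelihood direction — e.g. the
K = I, single-record case where σ²ₐ and σ²ₑ are not separately identifiable.

Because every record carries exactly one animal and one PE level, the PE
equations are diagonal after ordering and are **absorbed analytically**
before factorization: solutions, the restricted likelihood, tr(C_pepe), and
the log-determinant are recovered exactly through the Schur identities,
while the factorized system shrinks to the fixed + additive equations.
This is an exact reformulation, not an approximation.

## GEBVs, accuracy, and the weighted loop

The MME are solved by dense Cholesky at desk scale; prediction-error
variances come from the additive block of the coefficient-matrix inverse.
Accuracy is the PEV-based individual reliability square root,
r = sqrt(1 − PEV/((1+F)σ²ₐ)), averaged over recorded animals. Because the
literature often leaves "accuracy" undefined, the method-comparison report
also includes the correlation between predicted and true breeding values
whenever a simulated truth exists; the replicated ordering study uses that
truth correlation.

The weighted single-step GWAS loop runs, per iteration t:

1. G(t) = Z D(t) Z′ λ (D(1) = I), blended, inverted, assembled into H⁻¹;
2. GEBVs solved from the MME;
3. SNP effects back-solved: û = λ D(t) Z′ G(t)⁻¹ â_g;
4. weights updated: dᵢ(t+1) = ûᵢ² · 2pᵢ(1−pᵢ);
5. weights rescaled to constant trace tr(D) = M (floor 1e−8 per weight);
6. repeat (default 3 iterations).

**Back-solve and the genetic base.** Step 3 uses the *unblended* weighted
G so that Z û reproduces the GEBVs of genotyped animals. Since the
centered G annihilates the all-ones vector, the GEBV mean (the arbitrary
genetic base) is not expressible through SNP effects; the implementation
computes the minimum-norm solution through the SVD of Z(λD)^½ — avoiding
the squared condition number of forming G⁻¹ — and reproduces the
*base-centered* GEBVs to machine precision. This is the correct
invariance: adding a constant to every breeding value changes no SNP
effect. If the weighted G loses further rank (e.g. duplicate genotypes),
the reconstruction is restricted to its range and a warning is emitted.

**Window scan.** For each anchor SNP the window is the run of consecutive
same-chromosome SNPs within `window_bp` (default 520,000 bp, an LD-decay-
derived span) of the anchor. The window genetic value a_w = Σ Zⱼûⱼ across
genotyped individuals gives the scan statistic Var(a_w)/σ²ₐ × 100 with the
population (n-denominator) variance; an n−1 option exists. Sliding
per-SNP-anchored windows are the default because reported significant
regions sit at arbitrary offsets; a non-overlapping tiling is available.
Windows at or above 1.56% of the additive variance (a 50-fold enrichment
over 0.031%, the naive per-window share) are significant; overlapping
significant windows merge into regions. The scan uses the final
iteration's effects by default (configurable). Gene annotation is a local
half-open interval overlap against a user-supplied BED/GFF3; no network
queries.

## LD decay

r² is the squared Pearson correlation of gene-content vectors — the
genotype-based analogue of haplotype r², equal to it under random mating
and the reproducible desk-scale choice. All intra-chromosomal pairs within
1 Mb (configurable) are binned by distance (10 kb default); the decay
distance is the first crossing of the binned mean below r² = 0.2, linearly
interpolated between adjacent bin midpoints. Bins without pairs report
NaN, not zero.

## The synthetic data generator

`simdata` emulates a closed nucleus herd with repeated litter records:

- **Pedigree**: discrete generations, hierarchical random mating (each
  sire mated to `dams_per_sire` dams, `offspring_per_dam` offspring of
  alternating sex).
- **Genotypes**: biallelic SNPs at uniform random positions on 18
  autosomes (default 100 Mb each); founder alleles independent Bernoulli
  draws at U(0.05, 0.5) frequencies; gene dropping with Haldane
  recombination at 1 cM/Mb. LD therefore arises only from family
  structure and drift, not from an ancestral coalescent — decay with
  distance is present but shallower than in a real herd.
- **Phenotypes**: true breeding values are QTL effects at chosen markers,
  each scaled to a requested share of σ²ₐ, plus a genome-wide background
  (small normal effects at every non-QTL marker) for the remainder.
  A pedigree-recursion polygenic term is available instead, but it makes
  the genomic relationships pure noise for that variance share — a
  structure no real genome has — so the marker background is the default.
  Effects are scaled to the realized variance across the simulated
  pedigree. Each non-founder female receives `n_parities` records with a
  shared permanent-environment effect, random year-season levels, parity
  and year-season fixed effects (SD 0.3 each), and iid residuals.
  Component targets default to (0.9, 0.68, 5.49), i.e. h² ≈ 0.127 — a
  total-number-born-like trait. Phenotypes are Gaussian by default;
  rounding to non-negative integers is available for litter-count realism.

What passing tests on this generator show: the estimators and the scan
recover parameters and planted QTL under the model's own assumptions at
realistic sample sizes. What they do not show: robustness to genotyping
error, selection, non-random mating, maternal effects, or real LD
structure, none of which are simulated.

## Study sizes in the benchmark suite

The replicated studies (`singlestep.studies`) run at deliberately scaled
sizes chosen as the smallest that give the estimators realistic operating
characteristics: ~1,575 sows × 3 parities for heritability recovery;
~1,200 sows (80% genotyped) with 1,500 SNPs on five 50 Mb chromosomes for
the method comparison and window-scan studies. Chromosomes shorter than a
few tens of Mb are avoided because near-zero recombination lets gene
dropping produce duplicate genotypes, which adds null space to G. The
method-ordering study plants one major QTL (30% of σ²ₐ) plus five moderate
ones (10% each): under a single-QTL + infinitesimal architecture the
squared-effect weighting plateaus or dips by iteration 3 (a known
behaviour of the scheme), whereas the monotone iteration gains reported
for strongly QTL-influenced litter traits reproduce under this
QTL-dominated architecture.

## Known limitations

- Dense factorizations bound practical problem size to a few tens of
  thousands of equations; no APY or iterative solvers.
- Single-trait only; no genetic correlations, no Gibbs sampling.
- The exact HWE test is the standard two-sided conditional test without
  the mid-p variant.
- Parentage checking is the opposing-homozygote conflict rate only, not a
  full assignment algorithm.
- No haplotype phasing or imputation; residual missingness is
  mean-imputed.
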