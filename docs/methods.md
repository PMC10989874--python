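# Methods

This note documents the statistical models, algorithms and numerical choices
behind `regengwas`, and what the synthetic study generator does and does not
emulate.

## The analysis problem

The pipeline targets GWAS of *in vitro* regeneration traits scored from
semantic segmentation masks of plant stem cross-sections. Each mask labels
pixels as background, unregenerated stem, callus or shoot; the traits are
the proportions of *plant* pixels (stem + callus + shoot) occupied by callus
("callus area") and shoot ("shoot area") at weekly timepoints. Two features
dominate the statistics: the mapping population is a wild, strongly
structured collection of clonally replicated genotypes with very fast LD
decay, and the traits are zero-inflated right-skewed proportions (many
genotypes regenerate nothing at all). The pipeline therefore combines four
complementary association strategies — a Gaussian linear mixed model on
transformed nonzero values, a logistic mixed model on the zero/nonzero
dichotomy, windowed SKAT with permutation p-values on untransformed values,
and post hoc ART combination of single-SNP p-values — followed by shared
multiple-testing tiers, 30 kb peak deduplication and nearest-gene
assignment.

## Trait extraction and preparation

`mask_class_proportions` excludes background from the denominator; a mask
with zero plant pixels yields an explicit missing value rather than 0, so
imaging failures do not inflate the zero class. Replicates (two by design)
are merged by the arithmetic mean; a single surviving replicate passes
through unchanged, and a merged value is missing only when every replicate
is.

Transformations are per-trait recipes (the choice is configuration, not
automatic):

* **Box–Cox** on strictly positive values after structural zeros are
  dropped; the exponent is the profile-likelihood MLE (scipy), with the
  profile curve retained for inspection.
* **RB-INV**: z = Φ⁻¹((r − c)/(n − 2c + 1)) with Blom's c = 3/8; ties share
  their mid-rank. After any removal step, scores are re-ranked so the output
  remains exact normal quantiles.
* **Elbow removal** for PCA traits with a residual left clump: a Gaussian
  KDE (Silverman bandwidth, 512-point grid) estimates the frequency
  distribution; the cutoff maximizes the finite-difference second
  derivative on the segment between the last density valley and the
  rightmost substantial mode (≥ 5% of peak density). A unimodal density has
  no valley and triggers the explicit no-removal path, as does a candidate
  cutoff below the 1st percentile. The reference mode is the rightmost one
  because the spike to be removed can carry most of the mass, making a
  "global mode" rule degenerate.
* **Extreme outliers**: |z| > 4 on the transformed scale, configurable. The
  rule is deliberately conservative so genuine skew signal survives.

Every transform is monotone, so Spearman correlation with the raw trait is
1 and removal audits (counts per step) reconcile exactly.

**PCA traits**: centered, unscaled PCA (all inputs share the proportion
scale) over three batches — callus, shoot, or both, across the four
timepoints. Genotypes missing any batch trait are excluded; genotypes that
are zero for *every* trait in the batch (the recalcitrant spike) are removed
before the decomposition. Only PC1/PC2 become analysis traits; later
components carry little variance. Loadings follow a deterministic sign
convention (largest-magnitude loading positive).

## Relatedness and structure

The kinship is the centered GRM `K = ZZ'/m` over SNPs with MAF above a
configurable floor, matching GEMMA's default relatedness matrix; a
standardized variant is available by flag. Missing dosages are mean-imputed
per SNP. Structure covariates for SKAT are either genotype PCs ("P model",
eigenvectors of the GRM scaled by root-eigenvalues, default 5 components —
the count is a design choice) or an externally estimated ancestry-fraction
matrix read from TSV ("Q model"); ancestry estimation itself is out of
scope. LD decay is summarized as binned mean r² of dosage correlations for
intra-chromosomal pairs with a cubic spline through the bin means.

## Linear mixed model (continuous traits)

Null model y = Xb + u + e with u ~ N(0, σ²_g K), e ~ N(0, σ²_e I), fitted by
REML after one eigendecomposition of K rotates the covariance to diagonal
form, leaving a 1-D problem in δ = σ²_g/σ²_e. K is rescaled internally to
unit mean diagonal so h²_SNP = σ²_g/(σ²_g + σ²_e) is the fraction of trait
variance attributable to the relatedness matrix, and estimates are invariant
to the GRM's raw scale. Two numerical choices matter:

* The optimum in log δ is located by root-finding on the **analytic REML
  gradient** (a 49-point bracket scan followed by Brent's method on the sign
  change, boundaries checked explicitly). Minimizing the likelihood value
  directly stalls at ≈ 3×10⁻⁷ in log δ because near the optimum the
  likelihood varies below floating-point resolution; the gradient localizes
  it to ~10⁻¹², which is what makes h² exactly invariant to rescaling y.
* y is standardized internally (and estimates rescaled back) so the
  optimizer sees the same conditioning regardless of trait units.

Per-SNP tests are GLS Wald t-tests reusing the null variance components
(EMMAX-style), with per-SNP residual variance so that K = I reproduces OLS
t-tests exactly. Monomorphic SNPs are skipped with a reason, never assigned
p-values. Default per-trait filters: MAF ≥ 0.05, missingness ≤ 10%,
configurable. Traits with h²_SNP ≤ 0.10 are flagged by the heritability
screen but still scanned, so the gate can be overridden.

## Logistic mixed model (dichotomized traits)

Recalcitrance (trait = 0, with values below 10⁻¹² counted as zero) is
modeled by a logit-link GLMM with the same kinship, fitted by penalized
quasi-likelihood: alternate a logistic working response with an LMM solve,
estimating σ²_g by REML on the working response each outer iteration, until
fixed effects change < 10⁻⁶ (max 50 iterations; non-convergence is flagged
on the fit). Separation (fitted probabilities pinned at 0/1) raises an
error advising covariate reduction. Per-SNP inference is the efficient
score test U = g'(y − μ̂), Var(U) = g'Pg with P the null projection; Wald
p-values come from refitting with the SNP in the fixed effects and are
reserved for SNPs flagged by the score scan or round-1 ART windows. In that
two-round path the polygenic variance is held at the null estimate: per-SNP
re-estimation occasionally collapses the variance component under strong
signals and destabilizes the Wald p. The reported h²_SNP for the binomial
family is on the latent logistic scale, σ²_g/(σ²_g + π²/3).

## Windowed SKAT with empirical p-values

Windows of 3 kb staggered by 1 kb tile each chromosome (anchored at
position 1; empty windows dropped; consecutive windows overlap by
width − step). The statistic is Q = r'G_w W²G_w'r with r the residuals of
the (possibly untransformed) trait on covariates plus structure PCs, and
W = diag of Beta(1,25) density at each SNP's MAF (SKAT's default weighting;
flat weights by flag). Permutation p-values are the reason untransformed
traits are admissible here: the null distribution is generated by the data.

The parametric p-value is the tail of Σλᵢχ²₁ with λ the nonzero eigenvalues
of σ̂²·W G_w'(I−H)G_w W. The tail probability is computed by numerical
inversion of the characteristic function (Imhof's integral) with three
numerical safeguards: eigenvalues jointly carrying < 10⁻⁴ of the spectrum
mass are dropped (they stall the integrand's amplitude decay without moving
the probability); the oscillatory integral is summed over half-period
panels with 24-point Gauss–Legendre, terminated by an analytic
integration-by-parts tail correction whose residual bound must fall below
10⁻¹¹; and single-eigenvalue or equal-eigenvalue spectra use the exact
scaled-χ² closed form. The Liu et al. four-moment approximation is the
flagged fallback if inversion fails. The implementation was validated
against high-precision oscillatory quadrature (agreement ≈ 10⁻¹²) and
Monte Carlo.

Empirical p-values use Freedman–Lane residual permutation: r is permuted,
re-projected against the covariate hat matrix, and Q recomputed (one small
matrix product per permutation via M = W G_w'(I−H)). p = (b+1)/(B+1). Only
windows whose parametric p passes a gate (default 10⁻³) earn permutations;
B escalates through stages (default 10³ → 10⁴ → 10⁵) and stops early when
the Clopper–Pearson 99% interval for the exceedance probability excludes
the significance level (default Bonferroni over windows); reaching B_max
with the interval straddling sets converged = False. Each window draws from
an RNG stream keyed by (seed, CRC32(chromosome), window start), so results
are bit-identical for any worker count or scheduling order.

## ART combination

Candidate 1 kb windows come from an anchor scan over single-SNP results: a
SNP with p < 10⁻⁵ having ≥ 5 *other* SNPs with p < 10⁻⁴ within ±500 bp
(501 bp excluded; thresholds strict) seeds a window centered on it. The
combined p-value truncates at k = ⌈L/2⌉ (the upper half of top-ranking
members; ties broken by position via stable sort). Conditional on the
(k+1)-th order statistic, the k smallest p-values are order statistics of
U(0, p₍ₖ₊₁₎), so T = Σᵢ≤ₖ ln(p₍ₖ₊₁₎/p₍ᵢ₎) ~ Gamma(k,1) independently of
p₍ₖ₊₁₎; augmenting with A = −ln F(p₍ₖ₊₁₎), F the Beta(k+1, L−k) CDF, gives
T + A ~ Gamma(k+1, 1) and the combined p is its upper tail. k = L reduces
to Fisher's method and L = 1 to the identity. A Monte-Carlo calibration
test (uniformity of combined p under independent uniform inputs for
L ∈ {2,6,10}) guards the closed form against transcription errors.
Members within a window are treated as exchangeable — defensible in a
population whose LD decays within ~2 kb. Known limitation: the combined p
is strictly monotone in the k smallest members, but raising the
truncation-boundary order statistic toward 1 can *slightly* strengthen the
combined evidence (the augmentation term dominates there); this is inherent
to augmenting with the boundary order statistic.

For logistic-mixed results ART runs in two rounds: round 1 on score-test
p-values; windows passing the window-count Bonferroni threshold get Wald
refits for their member SNPs; round 2 recombines on the Wald p-values, with
windows missing any member Wald p flagged incomplete.

Thresholds: conservative Bonferroni = α/n_tests; ART Bonferroni
= α/(genome bp / 1000). For 394 Mb of assembled genome at α = 0.05 the
latter is ≈ 1.27×10⁻⁷, versus ≈ 4×10⁻⁹ for ~13 million single-SNP tests.

## Peaks, tiers and genes

A tested locus (SNP position, or window midpoint for SKAT/ART) is a QTL
peak iff no other locus within ±30 kb has a strictly smaller p; equal-p
neighbors resolve to the leftmost. Peaks are labeled with the most
stringent tier they meet: conservative-Bonferroni, then BH FDR at q = 0.10
(statsmodels step-up over the full p vector), then ART-Bonferroni. Loci on
non-assembled contigs can be excluded by configuration before any
computation. Gene assignment: a peak inside a gene body takes that gene
(relation exonic vs intragenic-nonexonic when exon records exist; genes
without exon records are treated as single-exon models) with distance 0;
an intergenic peak takes the gene with the smallest boundary gap (ties: the
nearer TSS, then leftmost), relation 5′/3′ by strand, distance reported to
the strand-aware TSS, plus a flag for a boundary gap ≤ 5 kb. Both the TSS
distance and the boundary gap are reported because "distance to gene" is
ambiguous between the two conventions.

## Synthetic study generator

The generator supplies every input with known ground truth:

* **Genotypes**: Balding–Nichols — ancestral frequencies Uniform(0.05, 0.5),
  subpopulation frequencies Beta-distributed with divergence parameter FST,
  dosages Binomial(2, freq). Defaults: 6 subpopulations (matching the
  structure analysis of the motivating population) and FST = 0.1, a
  moderate divergence that makes uncorrected scans visibly inflated
  (λ_GC ≈ 1.7–2.8 in the calibration runs) while kinship correction
  restores λ_GC ≈ 1. Optional LD by adjacent-SNP copying with exponential
  distance decay (default off, reflecting near-zero LD beyond 2 kb).
* **Traits**: liability L = Σbⱼg̃ⱼ + u + Xβ + timepoint offset + ε with
  u ~ N(0, h²·K̃) (K̃ trace-normalized), variance budget
  Σb² + h²_poly + σ²_ε = 1 so the covariate-free liability is standard
  normal; the observed value is 0 below the threshold τ (zero fraction
  → Φ(τ)) and otherwise an affine squash of the exceedance into (0,1],
  befitting an area proportion. Defaults: h²_poly = 0.3, τ = −0.5 (≈ 31%
  zeros, inside the 7–90% range the motivating study spans across traits),
  two replicates with independent ε. Covariates (log-normal stem diameter,
  four phenotyping phases) are mildly confounded with subpopulation so that
  structure correction is genuinely exercised. Callus carries the planted
  causal/polygenic signal across timepoints; shoot is an independent
  nuisance trait that is near-absent at week 2, mimicking late shoot
  emergence.
* **Masks**: a contiguous disk of plant pixels with callus/shoot pixel
  counts rounded to the request (within one pixel), for exercising the
  trait-extraction contract.
* **Annotation**: non-overlapping toy genes with random strands.

One behavior of the generative model worth knowing: averaging replicates
*after* zero-censoring is nonlinear (a genotype with one censored replicate
contributes half its positive value), which couples the censoring indicator
to the genetic value and inflates the REML h²_SNP of the merged,
zero-removed trait well above the liability-scale heritability. The
estimator itself is unbiased on uncensored traits (verified by simulation
recovery); the inflation is a property of censored proportion traits and is
one reason the dichotomized (logistic) and untransformed (SKAT) routes
exist alongside the Gaussian one.

What the generator does **not** emulate: realistic chromosome counts and
lengths, pedigree/family structure, LD beyond the optional copying model,
segmentation noise (masks are exact), genotype calling error, and
trait-trait genetic correlations beyond the shared liability. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated generative model, not robustness to real imaging or calling
artifacts.

## Problem sizes and determinism

Calibration suites run at n = 300 samples with ~2,000 SNPs/windows;
recovery suites at n = 600 with 5,000 SNPs over 20 seeds; the demonstration
pipeline at n = 200 with 1,000 SNPs on two 500 kb chromosomes and a
permutation schedule capped at 5,000 — sizes chosen so the full suite runs
on a laptop in minutes while keeping Monte-Carlo error comfortably inside
the asserted tolerances. All randomness flows from explicit seeds through
`numpy.random.SeedSequence`; pipeline outputs are written with fixed float
formatting and are byte-identical across reruns and worker counts.
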