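# Methods

This note documents the statistical models, the synthetic-data design, the
numerical choices, and the limitations a user should know before trusting a
result on real data.

## Dosage calling

Read sampling at a biallelic site is modelled as binomial: an individual
with alternative-allele dosage `k ∈ {0..4}` produces an alternative read
with probability `f'(k) = (k/4)(1−e) + (1−k/4)e`, where `e` is the
per-read sequencing-error rate (default 0.002; any value in [0, 0.005]
reproduces the reference posterior tables at two decimals). The posterior
over the five classes uses a uniform prior by default; a Hardy–Weinberg
Binomial(4, p) prior is available (`hwe_prior`) but is not the default
because the reference posteriors are uniform-prior values. With zero reads
the prior is returned unchanged. Likelihoods are evaluated in log space so
the `e = 0` limit is exact: a class whose allele fraction is 0 with
alternative reads present gets posterior exactly 0.

Calls are posterior modes, masked when the maximum posterior is below the
threshold (default 0.85). Ties — and ties in the imputation mode — break
toward the lower dosage class: deterministic and conservative toward the
reference allele. Marker filters run in a fixed order (mean depth in
[10, 100] → MAF ≥ 0.01 from the called dosages → missing fraction ≤ 25%,
strict inequality for removal) and the QC report counts removals per rule.
Depth is interpreted as a per-marker mean. Removal of multi-allelic or
repetitive-region markers is an alignment-level concern outside this
package.

## Relationship matrices

* Additive: `Z = X − 4P`, `G_A = ZZ′/Σ_j 4 p_j q_j` (VanRaden-style
  normalisation at ploidy 4). Allele frequencies default to the sample but
  can be fixed externally, which makes subsetting commute with construction.
* Digenic dominance: per-marker quadratic `d(x) = C(x,2) − 3px + 6p²`,
  which has mean zero and is orthogonal to the linear covariate under
  Hardy–Weinberg dosages. The normaliser is the *exact* Binomial(4, p)
  variance of `d`, enumerated over the five classes — no closed form is
  assumed, and a test enumerates the same five outcomes independently.
* Epistasis: the Hadamard square of `G_A` (additive×additive only).
* Full tetraploid: one-hot indicators over the five classes per marker;
  `MM′` is computed class-by-class without materialising the n × 5m
  indicator matrix and rescaled to unit mean diagonal. The scaling only
  changes the units of the variance component, not predictions.
* RKHS: squared Euclidean distance between dosage rows, divided by its mean
  off-diagonal value so the bandwidth θ is dimension-free across marker
  counts, then `K = exp(−θD)`. Whether the distance is squared or scaled is
  a convention; since θ is re-estimated from data the choice is largely
  absorbed.

A PSD guard clips eigenvalues below −1e−8·λmax to zero with a warning.

## REML engine and field-trial adjustment

`fit_lmm_reml` handles `y = Xβ + Σ_k Z_k u_k + e` with independent iid
random terms: EM on Henderson's mixed-model equations (tolerance 1e−8 on
the relative change of every component, at most 500 sweeps; when the polish
is enabled EM hands over after 60 sweeps), followed by average-information
Newton steps accepted only when the restricted likelihood rises, with step
halving and a positivity floor at 1e−6·var(y). The floor keeps V invertible
in degenerate cases (e.g. literally duplicated plots). Fixed effects are GLS
at the converged components. Non-convergence is flagged, not raised.

Within-trial adjustment fits fixed genotype + reference-coded blocks and
random rows/columns within blocks; reference coding anchors the BLUEs to
the first block so a disturbance confined to another block is absorbed by
that block's dummy. Outliers are flagged at |standardised conditional
residual| > 3.5 (no published rule exists; removal is opt-in and counted).
Check genotypes participate in the fit but are dropped from the output.
Across-trial combination is OLS with fixed trial + genotype on the
within-trial BLUEs; a genotype seen in one trial is kept with a larger SE.
The two-step pipeline equals a single joint model exactly on balanced data
when the incidental row/column terms are dropped (`fit_rows_cols=False`);
with REML-estimated row/column variances the agreement is approximate, which
is why the equivalence test uses the OLS configuration.

Heritability uses the genotype-mean form
`H² = σ²_g/(σ²_g + σ²_gL/l + σ²_gT/t + σ²_ε/(lt))`; the residual at one
BLUE per genotype per trial is the genotype×location×year interaction and
absorbs within-trial error. For the components (3, 0.6, 0.4, 1.2) at
l = 3, t = 2 this evaluates to 5/6 ≈ 0.833 by direct arithmetic.

## Prediction models

Kernel models are sampled in each kernel's eigenbasis (one decomposition per
kernel; a Gibbs sweep is O(n²) per kernel), with scaled-inverse-χ² variance
priors: 5 prior degrees of freedom, scales chosen so the prior expected
variances split half the phenotypic variance evenly across genetic terms and
assign the other half to the residual — the partition rule common to
whole-genome regression software. Defaults are 10,000 iterations with 2,500
burn-in and thinning 1; chains are bit-reproducible per seed, and exact
location/scale equivariance of the sampler is covered by tests. The
full-tetraploid model uses a single variance for all 5m indicator effects.

Marker-effect models share a numba-compiled per-marker Gibbs sweep:
BayesA (per-marker scaled-inv-χ² variances), BayesCπ (spike-and-slab with
π ~ Uniform(0,1) via its Beta conditional; π is the *zero*-effect
proportion), Bayesian LASSO (exponential mixing on τ², λ² ~ Gamma(1.1, 0.1)
hyperprior, inverse-Gaussian conditional for 1/τ²). Under a pure-noise
trait π is only weakly identified — its posterior stays diffuse around 1/2 —
so null-behaviour checks use the median over seeds rather than one chain.

RKHS maximises the single-kernel REML profile likelihood over a θ grid
(default 0.1–4), eigendecomposing the kernel once per θ; degenerate
all-ones kernels at tiny θ get a 1e−8 ridge and a warning. The likelihood
is nearly flat below the data-generating θ (for small θ, `K ≈ 11′ − θD`, so
θ trades off against the genetic variance); bandwidth recovery is therefore
only assessable where the surface has curvature.

Predictions for unphenotyped individuals: kernel models extend each
posterior-mean genetic term through the joint kernel rows
(`g_all = K[:,T] K[T,T]⁻¹ g_T`, per kernel); marker models use
`X_test · posterior-mean b`. Marker centering and kernel construction use
all genotyped individuals; phenotypes of validation individuals are never
touched (a canary test corrupts them and asserts bit-identical
predictions).

## Cross-validation and CDmean

The default scheme mirrors a 105/42 split with 100 repetitions (both
configurable). CDmean follows the coefficient-of-determination approach:
with training block `G_TT` and variance ratio λ = σ²_ε/σ²_g (estimated once
by additive REML on all data unless supplied), the prediction covariance is
`W = G[:,T] P G[T,:]` with `P = A − A11′A/(1′A1)`, `A = (G_TT + λI)⁻¹`, and
CD of a validation individual is evaluated either directly (`W_ii/G_ii`) or
for its contrast with the population mean (default; the published variant
is not pinned down, so both are provided). The optimiser is steepest-ascent
exchange with restarts (default 5) because the CD surface has many shallow
local optima; on large panels each pass scores a bounded random subsample
of swaps to stay tractable. Only improving swaps are accepted, so the final
CDmean dominates every random start.

## GWAS

Scans are P3D: the polygenic null model (additive kernel) is fitted once by
REML via eigendecomposition; each marker then gets a GLS estimate and Wald
t-test (df = n − 2) in the rotated basis, fully vectorised across markers.
Monomorphic coded columns are skipped and flagged. The five codings follow
the gene-action table: additive 0–4; simplex/duplex dominance as 0/4
switches at ≥1 or ≥2 copies of the favoured allele, with reference-allele
versions obtained by the same rule on 4 − x.

Li–Ji effective tests: eigenvalues of the marker correlation matrix via the
n × n cross-product (only the nonzero spectrum is needed);
`Meff = Σ I(λ≥1) + (λ − ⌊λ⌋)`, with near-integer eigenvalues snapped before
the floor (the floor is discontinuous and numerical noise at λ = 2 − 1e−12
would otherwise inflate the count by ~1). On wide panels (n < m) Meff
routinely *exceeds* n — the rank-many eigenvalues sum to m and each
contributes 1 plus its fractional part, ≈ 1.5 per eigenvalue on random
panels; a 147-individual, 39k-marker panel therefore lands near
147 × 1.5 ≈ 220 effective tests. The genome-wide threshold is
`−log10(α/Meff)` reported at two decimals; Meff is computed genome-wide on
the additive coding and shared across codings. QQ calibration is summarised
by genomic-control λ and a bulk QQ slope.

The variance-explained regression is nested OLS: intercept + 3 PCs; + the
additive coding's significant markers; + each dominance coding's
significant set. R² is non-decreasing along the nesting by construction;
aliased columns are dropped with a warning and p ≥ n designs are rejected
with advice to prune.

## Population structure

PCA comes from the eigendecomposition of the additive relationship matrix
(scores = eigenvectors × √eigenvalues). Pairwise F_ST treats each
tetraploid as four allele observations (dosage/4 as its allele frequency)
and applies the allele-frequency-level Weir–Cockerham two-level ANOVA
estimator, combined across markers as a ratio of sums (not a mean of
ratios); estimates are clamped to [0, 1] with the raw value retained.
Groups below a minimum size (default 5) are excluded with a warning. The
exact estimator used by polyploid population-genetics packages is not
published in formula form, so this is a documented variant, not a clone.

## Synthetic data: what it emulates, and what it cannot

The generator draws ancestral allele frequencies uniformly on a
configurable band, drifts subpopulation frequencies by a Balding–Nichols
F-model (Beta with variance F·p(1−p)), and samples dosages
Binomial(4, p_subpop) — a diversity panel with weak, market-class-like
structure (default F = 0.01 over 4 groups, giving pairwise F_ST of a few
hundredths). Read counts invert the dosage caller's likelihood exactly:
uniform total depth over a band (negative-binomial optional; no published
depth distribution exists, only the accepted [10, 100] filter band) and
binomial alternative counts at `f'(x)`. Phenotypes sum additive, simplex-
and duplex-dominance (0/4 gene-action codings, centred at realized
frequencies) and additive×additive product components, each rescaled so its
realized variance equals its target exactly; plots add
genotype×location, genotype×year, per-trial genotype residual, block, row,
column and plot-noise draws over a row–column layout with complete blocks,
one plot per genotype per block. Everything is reproducible bit-for-bit
from one seed. Default trait: unit additive variance and unit per-trial
residual, which puts H² at 6/7 ≈ 0.86 over 3 locations × 2 years — inside
the high-repeatability range typical of multi-environment tuber-trait
trials.

**Limitation that matters.** Individuals are drawn independently given
their subpopulation frequencies: there are no pedigrees, sibs or clones,
and markers are unlinked. Consequently the *true* digenic-dominance and
epistatic relationships between any two simulated individuals are
essentially zero (they are squares of already-small additive
relationships), so non-additive genetic values are intrinsically
unpredictable for held-out individuals in this population — adding a
dominance kernel or switching to RKHS cannot systematically raise
validation accuracy here, regardless of how much dominance or epistatic
variance the trait carries. Family-blocked or near-clone populations do not
change this, because on such structures the additive and non-additive
kernels coincide where it counts. Real cultivar panels are different:
decades of shared parentage give them substantive digenic relationships,
which is precisely what lets dominance modelling pay off there. Passing
tests on this generator therefore demonstrate correctness of the machinery
(samplers, kernels, scans, thresholds) and *within-sample* dominance
detection (the matched GWAS coding reliably out-scores the additive coding
at causal loci), but validation-accuracy gains from non-additive kernels
are a property of related germplasm that this generator deliberately does
not simulate.

## Problem sizes used in the test-suite and drivers

Simulation-based tests run at 50–200 individuals and 200–2,000 markers with
seeded replicate counts of 10–20, and Gibbs chains of 1,200–4,000
iterations (10,000 where the check targets sampler-vs-closed-form
agreement); the analysis drivers use 147 × 2,000 with 3,000-iteration
chains and 10 cross-validation repetitions. These sizes were chosen so each
check isolates its property at comfortable statistical resolution; all
randomness is seeded, so every reported count and interval is exactly
reproducible.
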