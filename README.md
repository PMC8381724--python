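# tetragp

Genomic prediction and gene-action GWAS for autotetraploid crops, built for
genotyping-by-sequencing (GBS) panels such as tetraploid potato cultivar
collections. The package runs the full chain from raw allele read counts to
prediction accuracies and association scans, and ships a synthetic tetraploid
population generator so every step is testable end to end without external
data.

## What it computes

**Dosage calling.** A biallelic marker in a tetraploid carries 0–4 copies of
the alternative allele (classes AAAA…BBBB). Given `ref`/`alt` read counts the
posterior over classes is

    f'(k) = (k/4)(1 − e) + (1 − k/4) e,   k = 0..4
    P(k | ref, alt) ∝ prior_k · Binom(alt; ref + alt, f'(k))

with sequencing-error rate `e` and a uniform prior by default. Cells below a
posterior threshold are missing; markers are filtered on mean depth, minor
allele frequency and missingness, and imputed by the per-marker mode.

**Relationship matrices.** From the dosage matrix `X` (n × m):
additive `G_A = ZZ′ / Σ_j 4 p_j q_j` with `Z = X − 4P`; digenic dominance from
the HWE-orthogonal quadratic `d(x) = C(x,2) − 3px + 6p²`; additive×additive
epistasis `G_A # G_A` (Hadamard square); a full-tetraploid matrix from one-hot
dosage-class indicators; and a Gaussian kernel `K = exp(−θD)` on scaled
squared dosage distances.

**Prediction models.** Eight whole-genome models of `y = μ + g + ε`:
kernel GBLUP with 1–3 kernels (Add, A+D, A+D+Ep, FT) by Gibbs sampling;
RKHS with the bandwidth θ chosen by REML profile likelihood; and three
Bayesian marker-effect regressions `y = μ + Xb + ε` — BayesA (scaled-t),
BayesCπ (spike-and-slab, π estimated from the data) and the Bayesian LASSO
(double-exponential), with numba-compiled Gibbs sweeps.

**Field trials and heritability.** Two-step adjustment: within-trial genotype
BLUEs from a row–column model (fixed blocks, random rows/columns within
blocks, EM-REML with an average-information polish), then across-trial BLUEs.
Broad-sense heritability on a genotype-mean basis:

    H² = σ²_g / (σ²_g + σ²_gL/l + σ²_gT/t + σ²_ε/(l·t))

**Cross-validation.** Repeated hold-out (default 105 train / 42 validation)
with random or CDmean-optimised training sets (exchange algorithm on the mean
coefficient of determination of validation contrasts); accuracy is the
Pearson correlation between adjusted means and predicted genotypic values.

**GWAS.** P3D mixed-model scans under five gene-action codings (additive,
simplex/duplex dominance for either allele), a Li–Ji effective-test-count
threshold `−log10(α/M_eff)`, QQ calibration diagnostics, and a nested-R²
regression quantifying the phenotypic variance explained by each coding's
significant markers on top of the first three principal components.

## Worked example

The numbered drivers under `analysis/` run the study on a simulated panel of
147 tetraploid individuals × 2,000 markers (run them in order; outputs land
in `results/`):

```bash
python analysis/01_simulate_population.py
python analysis/02_call_dosages.py
python analysis/03_adjust_phenotypes.py
...
python analysis/08_population_structure.py
```

Selected output (trait simulated with substantial simplex-dominance
variance):

```
markers kept: 2000/2000 (depth -0, maf -0, missing -0)
non-missing call concordance with truth: 0.9879
tuber_count: H^2 = 0.926

Add       random  accuracy 0.328 +/- 0.033
A+D       random  accuracy 0.355 +/- 0.035

Li-Ji effective tests: 221.8 of 2000 markers -> threshold -log10 p = 3.65
                 design       r2_percent
             3 PCs only            11.09
    3 PCs + Add markers            39.40
3 PCs + Add + 1-dom-alt            61.41
```

Reading this: dosage calls from simulated GBS counts are ~99% concordant with
the truth; the trait is highly repeatable across the six trials; adding the
digenic-dominance kernel nudges predictive accuracy upward; and recoding
markers as simplex-dominant raises the explained phenotypic variance from 39%
to 61% — the signature of a dominance-controlled trait, which the additive
scan under-detects.

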