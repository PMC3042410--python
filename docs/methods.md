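# Methods

## Overview

`polyte` implements a ratio-based translatome analysis for polysome-gradient
expression data. The measured object is, per gene *g*, strain *s* and
biological project *p*, the translational efficiency

TE(g, s, p) = I(g, s, HP, p) / I(g, s, T, p),

the ratio of the summarized hybridization intensity in the heavy-polysome
pool to that in total RNA (LP can substitute for HP). Because each array is
normalized to a common average intensity, TE values are relative: they rank
genes within a strain and expose *relative* between-strain changes for a
given gene, not absolute initiation rates.

## The generative model (simulate)

The synthetic-data generator defines the study conditions every test and the
acceptance script run under.

**Truth.** Per gene, `log2 TE_wt = σ_te·z + c·(log2 ORF − mean)` with
`z ~ N(0,1)`, mean-centered so the genome-average log2 TE is 0, and
`log2 TE_mut = β · log2 TE_wt` exactly. β is the narrowing factor; the default
β = 1/1.30 makes the WT-on-mutant regression slope 1.30. The ORF-length
coupling `c = −0.20` (per log2 nt) encodes the inverse TE–ORF-length
relationship seen genome-wide. mRNA abundance is log-normal
(log2 mean 9, SD 1.2). LP-pool log2 TEs are a damped copy (×0.5) of the HP
TEs, compressed by the same β in the mutant.

**Measurement.** One array per {strain} × {HP, T (+LP)} × {project I–III} ×
{technical replicate 1–3} (36 arrays at defaults). Expected linear intensity
on a T array is proportional to abundance; on an HP array to
abundance × TE(strain). On the log2 scale the model adds: a fixed per-probe
affinity (SD 0.25, 4 probes/gene), a biological effect per
gene × strain × fraction × project (SD 0.06) shared by that RNA sample's
technical replicates, technical noise per probe × array (SD 0.08), and a
per-array scale offset (SD 0.08). All noise is log-normal, keeping HP/T
ratios unbiased in log space.

The magnitudes are the package's own calibration (no published values exist
for them): σ_te = 0.45 plus the coupling term gives a genome log2-TE SD of
~0.49, and the noise SDs keep replicate-MA variances small relative to the
between-strain MA variances — the regime in which a ratio pipeline is
informative at all. After pooling (3 projects × 3 reps) the residual noise
variance on log2 TE is ~0.006, so the regression slope recovers 1/β with a
measurement-noise attenuation of ~2%.

**Features.** 5'UTR lengths are log-normal with arithmetic mean 89 nt
(sdlog 1.0), ORF lengths mean 1385 nt (sdlog 0.65), 3'UTR mean 120 nt;
uORF counts are Poisson(0.36); 18% of genes are flagged essential; 0.5% carry
a structured-5'UTR (MFE) flag; categories are drawn from eight labels with
fixed probabilities (plus a 25% chance of a second label). Ribosome densities
scale as (ORF length)^−0.4 around 0.64 ribosomes/100 nt and peak ribosome
counts as density × length, giving the short-ORF / low-ribosome-load class
used by the LP cross-referencing.

**Ct tables.** qPCR simulation inverts the quantification: for configured
gradient proportions p_f and A280 weights w_f, the fraction Ct for the gene
of interest is placed `log2(p_f / w_f)` cycles away from the ΔΔCt = 0
baseline, so the forward pipeline recovers p_f exactly at zero Ct noise;
Gaussian cycle noise (SD 0.1 by default) is added per replicate reaction.

**Determinism.** All draws derive from a single `numpy` generator seeded from
`SimulationConfig.seed`; identical configs give identical outputs.

## Normalization

1. **Quantile normalization** within each (strain, fraction) array group:
   each column's values are replaced by the across-array mean of the sorted
   columns at their rank; fractional (tied) ranks interpolate linearly, so
   ties receive the mean of the tied reference values. Normalizing within
   groups — rather than across the whole cohort — equalizes arrays that probe
   the same RNA population while leaving genuinely different populations
   (polysomal vs total RNA) uncompared; whole-cohort quantile normalization
   would force those distributions together and flatten part of the HP/T
   signal. The whole-cohort variant remains available (`qn_groups="all"`).
2. **Array scaling**: every array is shifted in log2 to the grand mean of the
   per-array means (a multiplicative per-array factor), removing residual
   scale differences between groups. With centered true log2 TEs this step is
   the identity on noise-free data, which is what makes the pipeline's exact
   noise-free closure possible.
3. **Median-polish summarization** per gene of the log2 probes × arrays
   block: iterative row/column median sweeps fit
   `log2 I = μ + probe + array + residual`; the per-array summary is
   `μ + array effect`, so probe affinities cancel. Tolerance 1e-6 on the
   maximum residual change, at most 20 sweeps, midpoint medians for ties.
   With a uniform probe count per gene the sweeps run vectorized over all
   genes simultaneously (identical arithmetic, shared stopping test).
   Background correction (the RMA normal-exponential deconvolution) is
   deliberately omitted: it belongs to scanner-vendor preprocessing and the
   generative model produces background-free intensities.
4. **Technical-replicate averaging** on the linear scale (TE is a ratio of
   linear intensity summaries; a log-scale option exists), yielding one
   column per (strain, fraction, project).

## TE statistics

- **Pooled means (mode A)**: per strain, the ratio of the across-project mean
  HP intensity to the mean T intensity (`ratio_of_means`, default) or the
  mean of per-project TEs (`mean_of_ratios`).
- **Ratio statistics (mode B)**: per-project TE_mut/TE_wt ratios, averaged,
  with their SEM, plus a two-tailed pooled-variance Student t-test
  (df = n₁+n₂−2) comparing the TE triples. When both triples have zero
  variance the statistic is undefined; the test reports p = 1 for equal
  means and p = 0 otherwise and flags the gene, keeping classification
  total. Raw p-values are used for classification (matching the ratio +
  p ≤ 0.1 design); a Benjamini–Hochberg column is emitted for information
  only.
- **Classification**: down set = {mean ratio ≤ 0.71 and p ≤ 0.1}, up set =
  {≥ 1.4 and p ≤ 0.1}; monotone in both thresholds and α by construction.
- **MA statistics**: M = log2 I₁ − log2 I₂, A = ½(log2 I₁ + log2 I₂),
  sample variance of M (n−1).
- **Regression**: OLS of log2 pooled TE_wt on log2 TE_mut (orientation
  switchable). With the wider-spread variable as response the slope
  estimates 1/β; noise on the predictor attenuates it slightly toward 1.
- **Group ratios**: per-gene project-averaged TE_wt/TE_mut, averaged over the
  genes above (below) the genome-average WT TE; the genome average is the
  arithmetic mean of pooled WT TEs.

Both orientations of the low-TE dependency fraction are reported
(`low_wt_gt_mut` and `low_wt_lt_mut`): under the narrowing model low-TE genes
are translated *relatively better* in the mutant, so the `wt_lt_mut` reading
is the informative one; the complementary count is retained for completeness.

## Feature association

Group feature means ± SEM with a two-tailed test versus a reference set —
Welch's unequal-variance t by default (group sizes and variances differ
wildly between a ~100-gene set and a genome), with pooled-t and Mann–Whitney
options. Genes missing an annotation are dropped pairwise. Category
enrichment uses two-sided Fisher exact tests on 2×2 tables with Bonferroni
correction over the tested categories (those with ≥2 universe members) and
reports log2 fold enrichment of category frequency in the set versus the
universe. Essentiality uses the same Fisher machinery. The ribosome-density
cross-reference filters genes by peak-ribosome class (default 1–3) plus a
density or ORF-length ceiling and summarizes LP-based TEs per strain.

## qPCR

ΔΔCt = (Ct_frac,GOI − Ct_frac,18S) − (Ct_total,GOI − Ct_total,18S); relative
quantity 2^−ΔΔCt (amplification efficiency fixed at 2). Replicate reactions
are averaged in Ct space (arithmetic mean of cycles) before ΔΔCt, matching
standard practice; quantity-space averaging is available as an option.
Per-fraction quantities are multiplied by the strain's A280 gradient weights
and normalized to sum to 1, giving the mRNA's distribution over
{Mono, LP, HP}. The between-strain TE ratio is
(2^−ΔΔCt(HP−T)_mut / 2^−ΔΔCt(HP−T)_wt) × (w_HP,mut / w_HP,wt); with the
packaged weights the Ct-identical baseline is 0.114/0.308 ≈ 0.370. The
packaged mutant weight set sums to 1.001 as measured and is used without
renormalization (validation tolerance ±0.01). All outputs are invariant to
constant Ct shifts within a strain.

## What the synthetic data does and does not show

The generator reproduces the study *design* (strains, pools, projects,
technical replicates, probe structure) and the narrowing *model*, so passing
tests demonstrate that the pipeline recovers known parameters under realistic
multiplicative noise — not that any biological claim holds. Real data differ
in ways the model omits: intensity-dependent (banana-shaped) MA bias,
background and saturation, heavy-tailed TE distributions and outlier genes
(the model's Gaussian log-TEs make genes beyond ~3 SD — and hence large
classified gene sets at the 0.71/1.4 thresholds — rare), correlated probe
effects, mRNA-abundance changes coupled to translation, and partial
contamination between gradient fractions. Classification counts on synthetic
defaults are therefore near zero and are reported as computed; they are a
property of the Gaussian truth distribution, not a pipeline failure.

## Problem sizes and numerics

Tests and the acceptance script use 150–6000 genes with 3–4 probes per gene;
the acceptance script averages the slope and MA-variance ratio over five
seeds at 6000 genes. Quantile normalization is exact interpolation (no
iteration); median polish stops at max-residual change ≤ 1e-6 (≤ 20 sweeps)
for production use and tighter settings in oracle tests; on matrices with an
even number of rows or columns median polish may oscillate between
equivalent fixed points, which is why cross-implementation comparisons use
odd dimensions. Degenerate inputs (zero-variance t-tests, empty gene
selections, missing fractions, non-positive intensities) raise typed errors
or flagged conventions as described above rather than propagating NaNs.
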