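# Methods

## The analysis model

`ryescan` quantifies how genetic differentiation between two diverged
populations is distributed along the genome, and whether that
distribution is shaped by linked selection. The unit of analysis is the
non-overlapping physical window (default 10 Mb — on a multi-Gb cereal
genome this is 1–2 % of a chromosome, the natural resolution for sparse
GBS data). Per window it computes:

* **π** (per population): Σ_sites 2p̂(1−p̂)·n/(n−1), divided by window
  length, where p̂ is the ALT-allele frequency among the n non-missing
  alleles at the site. The n/(n−1) factor makes the per-site term an
  unbiased estimate of population heterozygosity and equal to the mean
  pairwise difference among sampled alleles.
* **d_xy**: Σ_sites [p̂₁(1−p̂₂) + p̂₂(1−p̂₁)] / L — mean between-population
  pairwise differences per bp. Insensitive to post-split diversity
  changes, which is what makes the d_xy–ρ contrast diagnostic.
* **Hudson F_ST** as a ratio of sums:
  1 − Σ(mean within-population heterozygosity) / Σ(between-population
  heterozygosity), summed over sites with at least two non-missing
  alleles in each population. Ratio-of-sums (not mean-of-ratios) is the
  robust choice in windows with 10–20 SNVs; negative estimates are kept
  (clamping would distort the percentile machinery). A per-window
  Weir–Cockerham alternative was considered and rejected: with highly
  unequal sample sizes and sparse windows its variance components are
  noisier, and the Hudson form factors exactly into the within/between
  sums the identity tests verify.
* **Z(F_ST)** = (F_ST − mean)/SD across windows (sample SD). The
  "expected value" in the standardisation is read as the across-window
  mean — a model expectation is not estimable from one genome scan.

Normalisation is by *physical window length*, not covered sites: with
reduced-representation data this yields the characteristic 10⁻⁶–10⁻⁷
per-bp magnitudes and keeps windows comparable when SNV density varies.
Windows with no usable SNV are *undefined* (NaN) and excluded from
means, quantiles and correlations — treating them as zero would
manufacture low-diversity outliers out of sparsity.

Missing genotypes are handled pairwise-complete per site (no
imputation). All internal coordinates are 0-based half-open; VCF's
1-based convention is converted only in the reader/writer, the single
place off-by-one errors can live.

## Recombination classes and outlier scans

ρ = 4N_e·r is consumed as a per-window input track (its estimation from
LD is an upstream, off-the-shelf stage); interval estimates are averaged
into windows weighted by overlap length. Windows at or below the
genome-wide 0.25 quantile of ρ are *low*-recombining; above the 0.75
quantile, *high*; ties go to the lower class. The quantile is computed
genome-wide rather than per chromosome: the low-recombining blocks of
interest are large pericentromeric regions whose size varies between
chromosomes, and a per-chromosome split would force 25 % low windows
onto chromosomes that lack such a block. The classification is
rank-based and therefore invariant to monotone rescaling of ρ.

Outliers are windows *strictly above* the 0.95 linear-interpolation
quantile — genome-wide on Z(F_ST), and within each recombination class
on raw F_ST for the stratified scan (the Z-transform is monotone, so for
a fixed window set the genome-wide flags are identical either way; both
columns are emitted). Stratified scanning asks "which windows are
extreme *given* their recombination environment", removing the
low-recombination confound. Per-class results report both the fraction
of class windows and the fraction of all outliers, since either
denominator may be wanted. Correlation p-values are the t-transform of
Pearson r, uncorrected — the panel is descriptive.

## GO enrichment

Genes are assigned to windows by start position (each gene counted
exactly once). Genes in outlier windows form the study set; all
annotated genes the background. Terms with fewer than 5 study genes are
excluded before testing; each remaining term gets a two-sided Fisher
exact test, and p-values are Benjamini–Yekutieli adjusted — BY rather
than Benjamini–Hochberg because GO terms share genes, so arbitrary
dependence must be tolerated. The adjustment runs once across all tested
terms (not per GO class). The ontology graph is not traversed: terms are
tested exactly as annotated, matching the flat gene→term tables GBS
studies typically distribute. The enrichment ratio a/(a+c) is the share of a term's
genome-wide genes that lie in the study set; results also carry a raw-p
significance column since summary counts in the literature are sometimes
quoted at raw p < 0.05.

## The synthetic-data generator

The generator's job is to produce data with the statistical structure
the analysis assumes, with recorded truth, at desk scale.

* **Recombination landscape**: per chromosome, a contiguous central
  block covering a uniform 25–50 % of its windows draws ρ from
  U(0.2, 1.5) while flanks draw U(5, 15) — block windows are strictly
  below all flank windows, emulating large pericentromeric
  low-recombining regions. A noisy proportional cM/Mb map is attached.
* **"Low-ρ" windows** are then defined by the same genome-wide
  0.25-percentile rule the analysis uses, so truth classes and
  reconstructed classes coincide by construction.
* **Allele frequencies**: ancestral p ~ Beta(a, a) with a = 0.5
  (U-shaped, SFS-like) — a neutral-equilibrium stand-in that avoids a
  coalescent. In low-ρ windows p is shrunk toward its nearest fixation
  boundary by the diversity-scaling factor, reducing expected
  heterozygosity (hence π and d_xy) by roughly that factor. Population
  frequencies are independent Balding–Nichols draws
  Beta(p(1−F)/F, (1−p)(1−F)/F) with F_w = base F_ST, multiplied by the
  linked-selection multiplier (capped at 0.99) in low-ρ windows; this
  parameterisation gives E[F_ST] ≈ F_w exactly for the Hudson
  ratio-of-sums estimator, which is what the parameter-recovery tests
  exploit. Sites monomorphic at the frequency level in both populations
  are redrawn (SNV ascertainment).
* **Gene flow** is one-shot post-divergence admixture
  p₁′ = (1−m)p₁ + m·p₂ with asymmetric defaults (0.03 into the
  perennial-like population, 0.01 back) rather than per-generation
  migration — sufficient to depress realised F_ST below F_w
  qualitatively, and analytically transparent.
* **GBS noise**: i.i.d. per-genotype missingness (default 15 %, inside
  the 0–30 % filter band) and negative-binomial per-site depths (mean
  40, shape 8 → variance m + m²/k) so a realistic tail of sites falls
  outside the [10, 100] depth filter.
* **Annotation**: genes placed uniformly (length-weighted by
  chromosome), Poisson(2) background GO terms each; genes in designated
  windows receive the planted term with probability 0.8 versus 0.05
  elsewhere.

Defaults are the study-scale conditions: 7 chromosomes × 860 Mb → 602
ten-Mb windows, 158 + 120 diploid samples, ~15 SNVs per window, base
F_ST 0.2 with multiplier 2 and diversity scaling 0.5 in low-ρ windows.
Examples and most tests run a 6 × 100 Mb (60-window) genome, which
preserves every qualitative property at a fraction of the cost;
replicate-based checks use 50 + 50 samples.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: linkage disequilibrium within windows
(sites are independent given frequencies), spatially autocorrelated ρ
beyond the block structure, site-frequency distortions from real
demography or selection, sequencing error, depth–missingness coupling,
paralogy artifacts, or any GO hierarchy. Tests demonstrate estimator
correctness and pipeline recovery of planted structure, not robustness
to those real-data complications.

## Numerical and interface choices

* Filters: missingness is a strict inequality (exactly 30 % missing is
  removed); depth bounds are inclusive; "biallelic" requires single-base
  REF/ALT *and* both alleles observed among called genotypes;
  multiallelic records are dropped, not decomposed. Site depth uses
  INFO/DP when present, else the mean of per-sample DP. The filter
  report keeps X (input), Y (removed) and per-rule counts (a site can
  fail several rules, so rule counts may exceed Y).
* "Intergenic" is purely coordinate-based non-overlap with gene
  intervals — deterministic and annotation-version-independent; no
  effect-prediction engine.
* Quantiles are numpy's linear-interpolation quantile throughout.
* Degenerate inputs fail loudly: constant F_ST cannot be Z-transformed;
  a zero Fisher margin returns p = 1 with undefined odds; an all-equal ρ
  track classifies everything intermediate with a warning; classes with
  fewer than 5 defined windows are skipped in the stratified scan.
* Inbreeding: F = (O_hom − E_hom)/(N − E_hom) per individual, with
  E_hom from its own population's allele frequencies at its non-missing
  sites; group contrasts use the two-sided Wilcoxon rank-sum test with
  Bonferroni adjustment.
* Determinism: every stochastic stage draws from its own seed-derived
  stream; identical config + seed reproduces every output file
  byte-for-byte (the manifest digests verify this).

## Known limitations

Single-threaded and in-memory by design — at 10 Mb windows even a 7 Gb
genome is a few hundred rows, and GBS matrices are small. No haplotype
statistics, no sliding windows, no ρ estimation, no GO graph
propagation, no plotting beyond TSV/BED outputs. The Hudson estimator's
small bias at very low per-window SNV counts (< ~10) is visible in the
parameter-recovery regression if the SNV filter is relaxed; the
windowed truth-recovery test therefore conditions on ≥ 30 SNVs.
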