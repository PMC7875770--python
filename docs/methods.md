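# Methods

This note documents the statistical models implemented in `varscape`, the
choices made where the design was genuinely open, and what the synthetic
data generators do and do not emulate.

## Singleton clustering: exponential-mixture model

For one individual *i*, every singleton SNV (allele count 1 in the defining
sample subset, carried as a heterozygote) gets a nearest-neighbour distance
*d*: the bp gap to the closest other singleton of the same individual on the
same chromosome (minimum of the gaps to the previous and next singleton;
chromosome boundaries are never crossed; a chromosome holding a single
singleton contributes no distance). The distances are modelled as a
K-component mixture of exponentials

    f(d) = Σ_k λ_k (1/θ_k) exp(−d/θ_k),   θ_1 < θ_2 < … < θ_K,

where θ_k is the component **mean** distance (scale). The scale
parameterization, rather than rate, is what makes "component 1" the
short-range clustering process: components are reported in ascending θ.

**Estimation.** EM with responsibilities r_jk = λ_k f_k(d_j)/f(d_j), then
λ_k = mean_j r_jk and θ_k = Σ_j r_jk d_j / Σ_j r_jk. Convergence is a
relative log-likelihood change below `tol` (default 1e-8, `max_iter` 2000);
ascent is asserted at every iteration. Because the component scales span
five orders of magnitude (a few bp to ~150 kb), initialization matters: the
primary start places θ geometrically between the 1st and 99th percentiles
of the distances, which reaches a 1.5 %-weight component at θ ≈ 5 bp that
equal-count block-mean initialization cannot see. Block means are kept as
the second restart and further restarts jitter the geometric scales by
exp(N(0, 0.5²)). The best converged restart by log-likelihood wins;
components are sorted by θ on output.

**Choosing K.** Fits for K = 1, 2, … are compared by the likelihood-ratio
statistic Λ = 2(ℓ_K − ℓ_{K−1}) referred to χ²(2 df); the search stops at
the first K with P > α (default 0.01) and returns the K−1 fit. The χ²
reference at a mixture boundary is not regularity-justified; it is
implemented as stated rather than corrected, because the selection rule is
itself part of the procedure being reproduced. On four-component synthetic
data (n = 50 000) the rule recovers K = 4 in ≥ 19/20 seeded replicates; on
single-exponential data it keeps K = 1.

**Classification.** Posterior p(k|d) = λ_k f_k(d)/f(d); hard labels by
argmax with ties to the smallest component index. d = 0 is a valid input to
the density and the classifier (the density is finite at the origin) but
not to the fitter: two singletons at identical positions in one individual
are malformed input. Note that hard-label accuracy is bounded by the Bayes
rate: with equal weights and θ = (10, 1000) the optimal rule itself is only
~97.3 % accurate, so accuracy checks use a 1000-fold scale ratio where the
optimal rate is ~99.6 %.

## Mutational spectra

Substitutions are collapsed to six strand-symmetric classes (C>A, C>G, C>T,
A>C, A>G, A>T) by reverse-complementing purine-reference substitutions
together with their trinucleotide context. CpG status (oriented C followed
by G) sub-stratifies the C>* classes; it is undefined for A-reference
classes. Spectra are class proportions over hard-assigned singletons per
component; empty components are emitted with NaN proportions, never
dropped. 96-context spectra and ancestral polarization are out of scope.

## Hotspots and feature regression

Hard-assigned singletons are pooled per ancestry group and counted in
non-overlapping 1-Mb windows anchored at position 0 of each chromosome
(0-based half-open). All declared windows are kept, zeros included, so the
hotspot threshold — the empirical 95th percentile of counts within a
(group, component) stratum — is genome-wide. Hotspots are counts **strictly
above** the percentile, so ties at the threshold (and constant count
vectors) are not hotspots. Fewer than 20 windows is an error.

Window counts are regressed on per-window mean feature signals by negative
binomial ML (log link) with variance μ + μ²/size; the reported dispersion
is the size parameter (statsmodels' NB2 α inverted). Feature values are
base-weighted means of bedGraph-style tracks over the window; windows with
a missing feature are dropped listwise; collinear or constant feature
columns are removed with a warning before fitting. The regression is fit
per ancestry group and component, not pooled. 95 % Wald intervals cover a
planted β₁ at nominal rate (≥ 88/100 replicates in the acceptance check)
and the fit agrees with a Poisson oracle to 1e-3 when counts are Poisson.

## Rare-variant sharing

A variant enters the carrier matrix when its full-sample carrier count
(individuals with ≥ 1 alternate allele, het or hom — a *sample count*, not
an allele count) lies in [2, 100]; indels, multiallelic records and
singletons are excluded. The filter runs over the full analysis sample
before any group split, so every pair shares one variant universe. Pairwise
sharing is the Jaccard index J = |A∩B|/|A∪B| (defined as 0 and logged when
the union is empty). Group-level summaries average J over all unordered
within-group pairs and all between-group cross pairs, after dropping
individuals with missing/"other" population labels and groups below 19
members; an optional fixed-size subsample without replacement per group
reproduces the sample-size robustness check. No size reweighting is
applied to between-group averages.

## pLOF depletion bootstrap

Per gene: L = retained pLOF variants per CDS bp, S = singleton proportion
among them. pLOF annotation (stop-gained, frameshift, splice-disturbing,
high confidence) is consumed as input; variants with allele frequency
above 0.5 % or inside the accessibility mask are excluded. Genes without
pLOF variants carry L = 0 and undefined S (excluded from S averages,
logged).

The null for a gene set matches CDS length: genes sorted by CDS length
(ties broken by gene id) are cut into equal-count bins of 1000 (the final
short bin stands alone); each of `n_boot` replicates draws, with
replacement and per bin, as many genes as the set contributes there, and
averages L and S. Empirical one-sided P values are the strict-inequality
proportions of replicates below/above the observed mean, floored at
1/n_boot; the fold change is observed over the bootstrap average. On null
sets the P values are uniform (KS p > 0.01 across 500 sets at
n_boot = 10 000) and a planted half-rate set yields p_low < 1e-3.

Singleton proportions per annotation category (with optional CpG
stratification) use the same table machinery; the stratified view exists
because aggregate and per-stratum comparisons can reverse when CpG
composition differs between categories (Simpson's paradox).

## Segment variant density

Biallelic SNVs are split common/rare at allele frequency 0.005 (≥ is
common) and coding/noncoding by exon intervals, and counted per contiguous
1-Mb segment. A terminal segment of length L < 1e6 is scaled by 1e6/L;
empty segments are dropped after counting and before adjustment. The
adjustment model is OLS with intercept,

    count = β₀ + β₁·C + β₂·A + count_adj,

on the coding proportion C and accessibility proportion A. Both covariates
get free coefficients: fixing the slope of A to one count per unit
proportion (a formulation the adjustment is sometimes written in) would be
dimensionally arbitrary. Z-scores are
residuals standardized over (non-empty) segments, computed after the
non-empty filter. Degenerate designs (constant C and A) fall back to
centred counts with a warning.

The concatenated analysis labels every analyzable base coding/noncoding ×
CADD tier (high ≥ 20, 10 ≤ medium < 20, low < 10; per-base score is the
maximum over alternate alleles), strings the bases of each of the six
classes together in genome order, and counts variants per 1-Mb of
concatenated coordinate, scaling the short final segment. A variant at an
unlabelled base is an error, not a silent drop.

## Synthetic data

Generators are pure functions of (config, seed).

* **Mixture distances** — the four-component preset uses λ = (0.015, 0.18,
  0.465, 0.34) and θ = (5, 2 000, 40 000, 150 000) bp: fixed representative
  values inside the reported ranges for the four processes (≈1.5 % at
  2–8 bp; 12–24 % at 500–5 000 bp; 43–49 % at ~30–50 kb; 31–37 % at
  ~125–170 kb). Generating labels are returned for recovery tests.
* **Coalescent singletons** — msprime, mutation rate 1.29e-8 per site per
  generation, uniform recombination 1e-8 standing in for a genetic map
  (the < 100 bp clustering statistic is insensitive to recombination-map
  detail, which acts on much larger scales). The default demography is the
  African-European out-of-Africa history of Tennessen et al. (2012),
  chosen because its scope — one African and one European population with
  strong recent growth — matches the simulated design (2 000 + 2 000
  haplotypes); the clustering baseline is sensitive to the strength of
  recent growth, which sets the external-branch length distribution. The
  three-population model of Gutenkunst et al. (2009) is also encoded and
  selectable as `ooa_3pop`, and a constant-size control supports the
  analytic E[singletons] = 4NeμL check.
  Singletons are defined within each population's haplotype sample (an
  allele shared with the other population still counts), haplotypes are
  paired uniformly at random into diploids, and nearest-neighbour
  distances ignore haplotype of origin. The statistic pools both
  populations' diploids.
* **Genotype matrices** — allele counts from a 1/i spectrum with optional
  planted within-group carrier clustering and an optional duplicated
  individual; serialized as sorted VCF v4.2.
* **Gene tables** — log-normal CDS lengths, Poisson pLOF counts at a
  per-bp rate (multiplied for planted sets), Bernoulli singleton flags.
* **Window features** — N(0, 1) covariates and NB counts via the
  gamma-Poisson mixture, variance μ + μ²/size.

What the generators do **not** emulate: reference-biased calling error,
recurrent mutation at hypermutable sites, linkage between the genotype
matrix sites, realistic gene-length/GC covariation, or real feature-track
autocorrelation. Passing tests therefore demonstrate the statistical
machinery (estimator consistency, calibration, exact accounting), not
robustness to those data artefacts.

## Problem sizes and numerics

The test suite runs the clustering baseline at 20 Mb, K-selection at
n = 50 000 × 20 replicates, bootstrap calibration with 500 sets at
n_boot = 10 000, NB coverage with 100 replicates of 2 000 windows, and the
constant-size control at 10 Mb × 20 seeds; `scripts/acceptance.py` runs the
clustering baseline at the full 100 Mb. Tolerances follow from Monte-Carlo
error at those sizes (e.g. ±0.10 percentage points ≈ three between-seed
standard deviations of the < 100 bp fraction at 20 Mb). Seeds fan out from
one global seed via `numpy.random.SeedSequence.spawn`; msprime seeds must
be strictly positive and below 2³¹.

## Known limitations

* The χ²(2) reference for the LRT ignores the boundary non-regularity of
  mixture testing; K can be conservative or anti-conservative in ways the
  published procedure shares.
* The NB regression treats windows as independent; real feature tracks are
  autocorrelated and standard errors would be optimistic on real data.
* `read_variants` loads genotype carriage densely; it is intended for
  subsample-scale analyses (thousands of samples, site-filtered input),
  not whole-callset traversal.
* Missing genotypes count as non-carriers in allele counts, a simplifying
  convention the VCF writer never exercises.
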