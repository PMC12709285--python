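# Methods

`ploidyscan` compares genomic footprints of positive selection between
diploid and autotetraploid populations sampled across an environmental
contrast (calcareous vs siliceous soil).  This note documents the models
and procedures, the choices made where the design was genuinely open, and
what the synthetic study does and does not establish.

## Statistical model and pipeline

### Genotypes and frequencies

Genotypes are allele *dosages*: the count of ALT (or, after polarization,
derived) alleles in a genotype call, an integer in `[0, ploidy]` with
ploidy 2 or 4 per sample.  Population allele frequency is
`sum(dosage) / sum(ploidy)` over non-missing samples, so diploid and
tetraploid populations are summarized on the same frequency scale while
contributing different chromosome counts.  Half-called genotypes (e.g.
`./0/0/1`) are treated as fully missing — the VCF standard gives them no
clean dosage semantics — and multi-allelic records are dropped with a
logged count.

Site filtering follows fixed rules: genotype cells below a minimum depth
(default 8x) are set missing; sites with more than a maximum missing
fraction (default 0.5; 0.1 for the association input) or below a
minor-allele-frequency floor (0 by default; 0.05 for association) are
removed.  Two mask layers guard against artefacts: genes with at least
five *fixed heterozygous* SNPs (every non-missing sample at dosage
ploidy/2) in at least two populations are masked as putative collapsed
paralogs, and sites where at least 20 samples exceed their own depth mean
plus two standard deviations are masked as repetitive/duplicated regions.
Depth statistics are per sample: sequencing effort varies by library, so a
pooled cutoff would mask deep libraries wholesale.

Ancestral-state polarization consumes a key of `P(REF ancestral)` per
site; sites are polarized only when the probability reaches 0.7 for one
allele, otherwise they stay `unknown` and are excluded from statistics
that require polarity (unfolded estimators) but retained elsewhere.

### Diversity: pi and Tajima's D

Per-site diversity uses the unbiased estimator `2k(n-k) / (n(n-1))` for
`k` derived copies among `n` sampled chromosomes; window pi divides the
per-site sum by window length in bp (50-kbp windows, minimum 10 SNPs), so
monomorphic positions count as zero.  Tajima's D uses the 1989 constants
with `n` equal to the downsampled chromosome count.  To remove
sample-size artefacts both statistics are computed after downsampling each
population to four individuals per site (uniform draw without replacement
among non-missing genotypes), the same scheme for pi and D so the two
remain comparable.  A separate chromosome-level mode draws a fixed number
of allele copies (default 12) per population and site by a hypergeometric
draw from the sampled copies; it returns frequencies, not genotypes, and
feeds the standardized fixation counts.

### Differentiation: Weir–Cockerham F_ST and Rho

Window scans within a ploidy use the two-population Weir & Cockerham
(1984) estimator at the allele-count level: with one-way ANOVA mean
squares `MSA` (among populations) and `MSW` (within) on 0/1 allele copies
and `n_c` the usual sample-size coefficient, the per-SNP components are
`a = (MSA - MSW) / n_c` and `a + MSW`.  Windowed F_ST is the ratio of
summed components (1-kbp fixed grid anchored at position 1, windows with
fewer than 10 SNPs discarded).  Ratio-of-sums is used rather than
mean-of-ratios because per-SNP ratios are wildly noisy and averaging them
biases windows upward; negative per-SNP components stay in the sums and
values are clamped to [0, 1] only at reporting.

Cross-ploidy comparisons need a statistic whose expectation does not
depend on how heterozygosity is packaged inside individuals.  Rho achieves
this by excluding the within-individual stratum from the identity
probabilities: with individual allele frequencies `y = dosage / ploidy`,
the within-population diversity `H_W` is the average probability that two
allele copies drawn from *different* individuals differ, the
between-population diversity is `H_B = p_A(1-p_B) + p_B(1-p_A)`, and

    Rho = (H_B - mean(H_W_A, H_W_B)) / H_B,

summed per window as a ratio of sums.  Because within-individual copy
pairs never enter, polysomic heterozygosity and inbreeding cancel and
diploid/tetraploid values estimate the same quantity — a property the test
suite checks by simulation (matched population-frequency divergence, 250
windows) and that also makes Rho coincide with the allele-count F_ST for
random-mating diploids.  A nested-ANOVA variant that estimates an
among-individual variance component and forms `s2_a / (s2_a + s2_b)` was
considered and rejected: under random mating the among-individual
component has expectation zero, so that ratio degenerates toward 1
regardless of divergence.

### Outlier scan, parallelism and method intersection

Per population pair, the top `ceil(0.01 N)` windows by windowed F_ST are
outliers (ties at the cutoff all included and logged; fewer than 100
finite windows is an error because the quantile is unstable).  Outlier
windows are annotated to gene models by >= 1 bp overlap (1-based inclusive
coordinates on both sides).  *Parallel candidates* are genes that are
outliers in at least two pairs covering at least two distinct genetic
lineages, so a single lineage cannot create "parallelism" through shared
drift.  The final *top candidates* are parallel F_ST candidates that are
also supported by at least one of the two orthogonal methods below; the
overlap of top-candidate sets between ploidies is tested with the
hypergeometric upper tail, with the universe defaulting to the genes that
overlap at least one analyzable window (the natural population of genes
that could have been detected; configurable because any universe choice is
a convention).  A one-sided permutation test (10,000 same-size gene draws
without replacement) checks whether candidates sit in unusually
high-recombination regions.

### Repeated-adaptation order statistics

Each lineage contributes one contrast (its calcareous/siliceous pair), and
each lineage's windowed statistic is rank-transformed to empirical
p-values (average ranks for ties, `p = rank / N` in `(0, 1]`).  For a
window with sorted p-vector `p_(1) <= ... <= p_(L)`, the combined
statistic evaluates the Beta order-statistic tail
`q_a = BetaCDF(p_(a); a, L-a+1)` for `a = 2..L` — the minimum is excluded
so one extreme lineage cannot drive significance — and combines the
minimum over configurations with a Dunn–Šidák correction,
`1 - (1 - min_a q_a)^(L-1)`.  This combined statistic is calibrated
against a Monte-Carlo null of iid uniform p-vectors (default 10,000
draws), FDR-corrected (Benjamini–Hochberg), and thresholded at q < 0.05.
`n_est`, the estimated number of repeatedly adapting lineages, is the
configuration `a` attaining the minimum.  The `alpha_adapt` knob (default
0.05) is retained on the interface as the nominal fraction of windows
treated as potentially adapted when interpreting the calibration; the
shipped null is the iid-uniform one, which the calibration tests show is
adequate at 3–12 lineages.

### Environmental association

The association stage is an explicit latent-factor regression, documented
as a simplified stand-in for ridge latent-factor mixed models: population
structure enters as the top-k principal components of the centred
population x SNP frequency matrix, and each SNP is fit by OLS

    freq ~ intercept + soil_PC1 + k factors

at the population level (the modelled unit is the population mean
frequency).  Missing frequencies are mean-imputed per SNP; SNPs constant
across populations are excluded and logged.  Two-sided p-values for the
soil coefficient are FDR-corrected; genes with at least three significant
SNPs (q < 0.1) inside their span become association candidates, a SNP in
two overlapping genes counting for both.  The number of factors defaults
to k = 4 in `association_scan` (appropriate at dozens of populations);
the pipeline default is k = 2, matched to the eight simulated populations
per ploidy so the model keeps residual degrees of freedom.  The known
failure mode of this construction — factors absorbing a true
environmental signal when structure and environment are confounded — is
inherited from the method it emulates and is exercised in the tests.

### Soil gradient

Soil tables carry pH (H2O and KCl), bioavailable Ca, total Ca/Mg/K/Na and
CEC (mmol/kg).  Columns incomplete for some populations are imputed by OLS
on the three always-measured predictors (the two pH values and
bioavailable Ca), fitted on complete rows only; observed cells are never
altered, imputed cells are flagged, and fewer complete rows than
predictors + 1 is a hard error.  The gradient score is PC1 of the
column-standardized table, with the sign fixed so the pH_H2O loading is
negative — calcareous populations (high pH, Ca, CEC) then have negative
scores regardless of the linear-algebra backend's sign convention.
Populations without soil data keep a missing score: they are excluded from
the association stage but retained in the selection scans.

### Sweep magnitude and breadth

For each top candidate gene and each pair in which it is an outlier, the
profiler extracts per-SNP Rho in the 100 kbp on each side of the gene
midpoint (regions with fewer than 20 SNPs are skipped; truncation at a
scaffold edge is flagged).  *Magnitude* is the highest raw per-SNP Rho in
the region minus the genome-wide mean Rho of that pair — deliberately
smoother-independent.  *Breadth* is measured on a fitted curve: local
linear regression with tricube weights, the span selected from a fixed
grid (0.10–0.90, step 0.05) by minimizing

    AICC = log(sigma^2) + (1 + tr(L)/n) / (1 - (tr(L) + 2)/n)

with `L` the smoother matrix, evaluated on a 1-kbp grid.  The threshold is
twice the *background* Rho (mean per-SNP Rho in the 200 kbp beyond the
region on each side; genome-wide mean as a flagged fallback when no
flanking SNPs exist), and breadth is the bp length of the contiguous
above-threshold interval containing the curve maximum, with linear
interpolation at the crossings — zero (flagged) when the peak is below
threshold, capped at the region length (flagged) when the curve never
drops below.  Multi-modal curves therefore measure only the peak's own
component; side bumps are ignored, which is the conservative reading of a
single-sweep model.  Dense regions are thinned to at most ~600–1000 evenly
spaced SNPs before fitting, which leaves the curve essentially unchanged
while bounding the O(n^2) smoother cost; magnitude always uses the raw,
unthinned points.  Breadth is reported in bp (with a kbp display in
summaries).

### Fixation and allele-frequency comparisons

A SNP shows *complete allele frequency divergence* for a pair when one
population's frequency is exactly 0 and the other's exactly 1, counted
inside the 1-kbp windows overlapping the gene.  Strict equality is the
point: near-fixation (0 vs 0.96) does not count.  Per-gene averages
include a pair only when the gene is an outlier in that pair, and
everything is computed both on all sampled chromosomes and after the
12-chromosome subsample, because raw fixation counts are confounded by the
number of chromosomes sampled (tetraploid samples carry twice as many
copies, making spurious sample-level fixation rarer).  Allele-frequency
distributions around candidates (gene ± 2 kbp) are summarized per soil
class and oriented, for display only, so the siliceous class carries the
higher mean.  Relative differentiation is the gene's mean windowed Rho
divided by the pair's genome-wide Rho, averaged over qualifying pairs.

### Adaptation modes and selection-strength bins

Mode assignments (gene x quartet: de novo / standing / migration /
neutral, with the most likely selection coefficient `maxSel` from the bin
set {0.0001, 0.001, 0.01, 0.05, 0.5}) are *consumed* from a TSV — the
composite-likelihood fitting that produces them is out of scope, and the
file format is the contract that real output and the synthetic fixture
both satisfy.  Quartets are all unordered pairs of lineage-distinct
contrasts within a ploidy.  Neutral cases are excluded from all tallies.
Ploidy contrasts per mode (mode vs rest) use the 2x2 chi-square with
Yates continuity correction,

    N (|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)),

clamped to zero when `|ad - bc| < N/2`, plus Fisher's exact test
(two-tailed).  The continuity-corrected form is used because it exactly
reproduces published reference statistics for tables of this size.

### Protein-interaction degree test

Degree (number of distinct interaction partners after symmetric
deduplication, self-loops dropped) proxies pleiotropy.  No combined-score
threshold is applied by default.  Candidate genes map to proteins through
a 1:1 table (unmapped genes reported and excluded); the test statistic is
the mean candidate degree against a null of 10,000 same-size draws without
replacement from the full degree table, one-sided, with
`p = (1 + #{null >= observed}) / (n_perm + 1)`.

## Synthetic study

The generator emulates the paired design: two ploidies, several lineages
each, one calcareous/siliceous population pair per lineage.  Allele
frequencies follow a two-level Balding–Nichols hierarchy: an ancestral
frequency per SNP from a symmetric Beta(0.8, 0.8), a lineage frequency
from BN(F_lineage = 0.15), and a population frequency from BN(F_pop =
0.05).  Genotypes are binomial in the ploidy; 5% of genotypes are set
missing uniformly; depth is Poisson with mean 25.  Defaults: 4 lineages
per ploidy, 6 individuals per population, 6 scaffolds of 300 kbp, 0.02
SNPs/bp — enough windows for stable 1% quantiles and enough SNPs per 1-kbp
window to survive the minimum-SNP rule, while a full pipeline run stays
around half a minute.

Sweeps are planted at chosen genes: in every siliceous population of the
affected ploidies, the derived frequency is pushed toward a target by
`gamma(s) = s / (s + 0.01)` under a triangular kernel of half-width 20 kbp
around the gene midpoint, which creates the sweep-shaped track the
profiler needs.  The target is 1 for diploids and the *tetraploid
frequency cap* (default 0.85) for tetraploids; the cap is enforced on the
realized sample too (sampled dosages are reduced until the population
frequency is at or below the cap), a hard-cap reading of the
dominance-driven plateau at intermediate frequencies expected under
polysomic inheritance.  Source modes are realized as frequency-sharing
patterns only — standing: one shared pre-split elevation reused by all
pairs; de novo: independent elevation per pair; migration: the first
pair's elevated frequencies copied to the others — sufficient for tally
and label tests, not a coalescent model.  Soil tables are drawn from
class-separated means (pH, Ca, CEC high on calcareous soil, K higher on
siliceous) so PC1 of the standardized table recovers the gradient;
per-gene recombination rates are lognormal; the interaction network is a
Barabási–Albert graph (heavy-tailed degrees) over gene-derived proteins
plus 200 extra nodes, with two genes left unmapped to exercise the
exclusion path.

What passing tests on this bundle do **not** show about real data:
there is no linkage disequilibrium outside the planted sweep tracks, no
coalescent noise in the sweep shapes, no reference bias, no genotyping
error model beyond uniform missingness, and the soil variables are
conditionally independent given the class.  Power and calibration results
transfer only to the extent that real data resemble the hierarchical
island model.

## Numerical choices

- Windows are half-open internally (0-based) and emitted 1-based
  inclusive; the fixed grid anchors at position 1 of each scaffold so
  window membership is `(pos - 1) // size`.
- Permutation p-values use the add-one rule and are bounded below by
  `1/(n_perm + 1)`; null means within 1e-9 (relative) of the observed mean
  count as >= so exhaustive draws give exactly p = 1.
- The Monte-Carlo calibration null of the repeated-adaptation scan is
  shared across windows; its sampling error is common to all windows, so
  uniformity checks use a null sample several times larger than the
  window count.
- Loess spans that leave no residual degrees of freedom
  (`tr(L) + 2 >= n`) are inadmissible; all positions identical is a hard
  error.  Span selection over a discrete grid replaces continuous AICC
  optimization: the criterion is flat near its minimum and a grid keeps
  the selection deterministic.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  configs; same seed, byte-identical bundle files and identical run
  manifests (timestamps are deliberately absent).

## Known limitations

- Only two-population contrasts are supported (no multi-population F_ST),
  and indels/multi-allelic sites are out of scope.
- The association stage is a PC-covariate regression, not a ridge
  latent-factor estimate; with strong confounding between structure and
  environment it is conservative.
- The mode-assignment consumer trusts its input bins; it cannot detect a
  mis-specified composite-likelihood upstream.
- Breadth of strongly multi-modal profiles reflects only the dominant
  peak's component.
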