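# Methods

This note documents the statistical models behind `popstruct`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that matter for
reproducing results.

## Data model

Genotypes are unphased, unordered diploid allele pairs over an
rsID-keyed SNP panel; one panel locus may carry more than two alleles
(every statistic is written for k ≥ 2).  Missing calls are excluded
locus-wise from all counts (pairwise deletion, the GenAlEx/GENEPOP
convention) and never imputed.  Samples map to subpopulations, which
nest uniquely in superpopulations; every analysis runs at either level,
or on the pooled sample.

## Diversity statistics

Per (population, locus): Ho is the fraction of heterozygous individuals
among non-missing calls; He = 1 − Σ pa² is Nei's gene diversity from the
observed allele frequencies (plain estimator by default — the unbiased
2n/(2n−1) variant is an option but is not applied silently); Shannon's
I = −Σ pa ln pa with natural logarithm and 0·ln 0 = 0; Wright's fixation
index F = 1 − Ho/He, undefined at monomorphic loci (He = 0).  Multi-locus
summaries report mean ± SE with SE = sd/√L over the L loci where the
statistic is defined, and the count of dropped loci.

Hardy–Weinberg proportions are tested by chi-square goodness of fit:
expected genotype counts n·pa² and 2n·pa·pb from the observed allele
frequencies, the statistic summed over all k(k+1)/2 genotype classes, no
continuity correction, df = k(k−1)/2.  Raw p-values are reported; a
Bonferroni column (across performed tests) is emitted for reference but
never used to filter.  No exact HWE test is implemented.

## AMOVA FST

The FST estimator is an allele-level analysis of molecular variance:
each individual contributes two alleles; the squared distance between
two alleles is 0 if identical and 1 otherwise.  With 0/1 distances every
sum of squares reduces to allele-count algebra — for n alleles with
per-allele counts c, the sum of squared pairwise differences is
(n² − Σc²)/2 — which is what the implementation computes; tests verify
it against a brute-force oracle that builds the full pairwise distance
matrix explicitly.  Variance components use the standard unequal-size
coefficient n₀ = (N − Σnp²/N)/(P−1); FST = σ²a/(σ²a + σ²w).  The
multi-locus value sums components over loci rather than averaging
per-locus ratios, which would be dominated by low-diversity loci.
Negative raw estimates are preserved in the result object but clamped to
[0, 1] in output matrices (the usual display convention).

Significance comes from permuting individuals (allele pairs intact)
among populations, p = (1 + #{FST\* ≥ FST})/(B + 1) with B = 999 by
default.  Weir–Cockerham θ (1984; ratio of summed a-components to
summed a+b+c over alleles and loci) is available via `estimator="wc"`
because "FST from AMOVA" is not a unique estimator across packages; on
clean two-population structure the two agree closely, and both are
exercised by the parameter-recovery tests.

Loci where the design degenerates for a given partition (fewer than two
populations with data, no within-population degrees of freedom) are
excluded from the multi-locus sums and reported as undefined per-locus.

## Nei's standard genetic distance

D = −ln(JXY/√(JX·JY)) with JXY, JX, JY the across-loci means of Σ xa·ya,
Σ xa², Σ ya².  Loci undefined in either population are dropped from the
means; populations sharing no alleles at any locus give +inf, written
through to outputs as `inf`.  D is symmetric and relabelling-invariant;
no triangle inequality holds or is asserted.

## Exact G-tests

Genic tables are allele × population counts (2n per individual);
genotypic tables are unordered-genotype × population counts.  The test
orders tables with the observed margins by G = 2 Σ O ln(O/E) and reports
the probability mass of tables with G ≥ G_obs under the multivariate
hypergeometric distribution.

* Complete enumeration whenever the table total is ≤ 30, or the table is
  2×2 with total ≤ 500.
* Otherwise a Metropolis chain on ±1 moves over random 2×2 subtables
  (acceptance ratio equal to the hypergeometric probability ratio),
  GENEPOP-style defaults: 10,000 dememorization steps, 100 batches of
  5,000 iterations; the standard error comes from batch means.

Ties count as ≥.  Enumeration uses an absolute tolerance of 1e−12 on the
table-dependent part of G; the chain tracks that statistic
incrementally, so it resets the accumulator at each batch boundary and
uses a relative tie tolerance (1e−9) that absorbs floating-point drift —
distinct tables differ in G by many orders of magnitude more.  Tables
with fewer than two informative rows or columns (e.g. monomorphic loci)
are undefined and excluded from combination.  Per-locus p-values combine
across loci by Fisher's method, χ² = −2 Σ ln pᵢ on 2L df; a per-locus
p of exactly 0 (possible only by enumeration rounding) propagates as an
infinity marker.

## Enrichment scores

For each risk allele and population: x risk alleles among the
population's n non-missing alleles, against K of N in the pooled sample
(the focal population included in the pool — the comparison is "to the
global average", and the deviations then sum to zero across populations,
which tests exploit).  One-tailed p in the direction of departure from
the expectation nK/N, score = −log10 p signed positive for enrichment
and negative for depletion, exactly 0 at the expectation, 0 with a flag
for globally monomorphic loci, capped at ±300.  The p-value is not
doubled and no multiple-testing correction is applied.

Heatmap ordering: agglomerative average-linkage (UPGMA) clustering on
1 − Pearson correlation between score vectors; zero-variance vectors get
the maximum distance 2 with a warning.  Leaves are ordered by a
traversal that visits the lower (lighter) subtree first, ties broken by
node index, so orders are deterministic.

## Polygenic risk scores

Individual score = Σ wᵢxᵢ / (2 Σ wᵢ) over the individual's non-missing
loci, with xᵢ the risk-allele dosage and wᵢ = 1 (unweighted) or
|ln ORᵢ| (weighted).  The normalization makes 1 the all-risk-homozygote
maximum and 0 the no-risk minimum in both modes, and makes the
unweighted psPRS equal the population's mean risk-allele frequency when
no data are missing — an identity used as a cross-module consistency
anchor in the tests.  Missing loci renormalize the denominator per
individual rather than being imputed.

The absolute value in the weighted mode is a deliberate design choice:
published panels sometimes list odds ratios < 1 for alleles labelled as
risk, and |ln OR| keeps weights positive and the [0, 1] normalization
valid.  It is a package convention, not an established standard; for
panels with all OR > 1 it coincides with ln OR.

psPRS differences are assessed by one-way ANOVA on individual scores and
Tukey's HSD (scipy's studentized-range implementation) for each
population pair; for two groups Tukey's p equals the pooled-variance
t-test p (q = t√2), which the tests verify.

## Principal coordinates

Classical scaling: B = −½·J·D²·J, eigendecomposition, coordinates
= eigenvectors · √eigenvalue for eigenvalues above a relative tolerance
of 1e−12.  Negative eigenvalues are reported but their axes dropped (no
Cailliez/Lingoes correction); percent explained is over the positive
total.  Each axis is oriented so its largest-magnitude loading is
positive, making outputs deterministic.  The pipeline feeds PCoA the Nei
distance matrix by default (FST optional); infinite Nei distances are
replaced by the largest finite entry with a warning before embedding.

## Synthetic generator

A two-level island model with Balding–Nichols divergence:
superpopulation frequencies are drawn Beta(p(1−F)/F, (1−p)(1−F)/F)
around the global frequency p with F = `fst_between_superpops`
(expectation p, variance F·p(1−p)); subpopulation frequencies are drawn
the same way around their superpopulation's value with
`fst_within_superpop`.  The multiallelic generalisation is the
equivalent Dirichlet draw.  Genotypes per individual: with probability
`inbreeding_f` the two alleles are copies of one draw, otherwise two
independent draws — reproducing {p² + Fpq, 2pq(1−F), q² + Fpq} in the
biallelic case.  Loci are independent (no linkage disequilibrium),
missing calls are masked uniformly at `missing_rate`, and everything is
reproducible from one seed.

The study-scale default mirrors the structure of the FTD risk-locus
study: 26 cohorts with the 1000 Genomes Phase 3 sample sizes
(N = 2504) in 5 continental groups, the published 32-SNP panel with its
odds ratios, global risk-allele frequencies implied by the published
combined-population minor-allele frequencies, and rs3922636 as a
triallelic locus.  Divergence defaults are
`fst_between_superpops = 0.08` and `fst_within_superpop = 0.02`, chosen
once to match the magnitude of published continental pairwise FST values
(≈ 0.02–0.13) and the much weaker within-ethnicity differentiation;
inbreeding and missingness default to 0.  Generic (non-study)
configurations draw global frequencies uniform in (0.05, 0.95) and
synthetic odds ratios log-uniform in [1.1, 3.5].

What the generator does **not** emulate: linkage disequilibrium between
loci, admixture (each sample belongs to exactly one subpopulation —
real AMR cohorts are admixed), ascertainment of the SNP panel, allele
dropout structure in real genotyping, and any association between
frequency and effect size.  Tests passing on synthetic data therefore
demonstrate correctness of the estimators under the stated model, not
robustness to those real-data features.

## Validation experiment sizes

The test suite and `scripts/acceptance.py` use these problem sizes,
chosen so the experiments are statistically conclusive at desk scale:

* AMOVA oracle equivalence: 100 random instances, ≤ 4 populations × ≤ 20
  individuals × ≤ 3 loci, with missing data; agreement to 1e−10.
* Markov-chain exact test vs enumeration: 2×2 tables with totals up to
  500; 30 batches × 1,000 iterations after 3,000 dememorization steps;
  agreement within 3 standard errors (the batch SE floored at the
  ideal-sampling binomial SE when the tail probability is below the
  chain's resolution).
* Parameter recovery: FST targets {0.02, 0.05, 0.15} with the 26-cohort
  study hierarchy and 200 loci, recovered within ±20%.  The recovery
  runs set the within-superpopulation divergence to zero so the
  between-superpopulation parameter is isolated; with both levels active
  the superpopulation-level estimate lies slightly above the
  between-level target because same-subpopulation allele pairs are more
  correlated.  Inbreeding f = 0.05 is recovered within 3 SE by the mean
  fixation index over 200 loci in one population of 500.
* Null calibration: HWE chi-square at n = 200, p = 0.3, 2,000
  replicates (rejection rate at α = 0.05 inside the 99% binomial CI);
  permutation FST on two populations of 20 with 99 permutations, 500
  replicates (super-uniform: rate ≤ α + 3 binomial SE).
* Study-scale pipeline runs use 99 permutations and a shortened chain
  (1,000 dememorization, 20 × 500); the GENEPOP-style defaults remain
  the library defaults.

## Known limitations

* The AMOVA permutation test permutes whole individuals; it does not
  test Hardy–Weinberg departures within populations.
* The Markov-chain exact test reports batch-mean standard errors, which
  understate autocorrelation for very short batches; batch sizes below
  ~500 iterations are not recommended.
* Weighted and unweighted risk scores share one normalization family; no
  attempt is made to calibrate scores across panels with different locus
  counts.
* PCoA of non-Euclidean matrices (FST matrices frequently are) discards
  the negative-eigenvalue part of the variance; the eigenvalue table
  reports it so the distortion is visible.
* The pipeline's 3-level structure (sub within super) is analysed one
  level at a time; no hierarchical 3-level AMOVA is provided.
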