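# Methods

This note documents the statistical model behind `dcmscan`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a maintainer should know about.

## Pipeline

Input is a phased, biallelic SNP matrix (2·n haplotypes × L loci) with a
variant map and, for the F<sub>ST</sub> component, a two-group sample
labelling. Stages run in a fixed order:

1. **Variant QC** — call rate ≥ 0.95, minor-allele frequency ≥ 0.05,
   Hardy–Weinberg exact-test p ≥ 10⁻³, duplicate (chrom, pos) removal.
   Filters apply sequentially in that order so per-filter counts are
   reproducible. The HWE test is the exact conditional test, two-sided by
   probability mass (the standard choice for SNP QC, and exhaustively
   enumerable for testing); it is computed on all samples.
2. **Relatedness (optional)** — method-of-moments IBD from IBS counts and
   sample allele frequencies, with negative component estimates truncated
   to 0 and renormalized; PI_HAT = P(IBD=2) + ½·P(IBD=1). Pruning removes,
   greedily, the sample in the most pairs above the threshold (ties by
   smallest sample id). **Off by default**: in a small closed herd —
   exactly what the simulator produces — background kinship is universal
   and sits near the usual 0.1 threshold, so greedy pruning removes most
   of the sample. On data expected to be mostly unrelated with a few
   close pairs, enable it (`QCConfig(prune_related=True)`).
3. **Statistics** (per chromosome, on post-QC data):
   - Weir–Cockerham (1984) two-population θ per SNP from genotype counts
     with the heterozygosity correction; negatives clamped to 0,
     cross-population-monomorphic SNPs missing.
   - Garud H1 = Σpᵢ² and H12 = (p₁+p₂)² + Σ_{i≥3}pᵢ² over full haplotype
     strings in sliding windows of 14 SNPs, step 1; the window value is
     assigned to the SNP at 0-based offset ⌊14/2⌋ (centred assignment;
     haplotypes with a missing allele in the window are excluded).
   - Tajima's D in non-overlapping 300-kb physical bins, every SNP in a
     bin carrying the bin value; bins without segregating sites are 0.
     The bin width is configurable; 300 kb gives ~12 array SNPs per bin
     at the simulated 25-kb spacing.
   - Per-site π = 2j(n−j)/(n(n−1)).
4. **Smoothing** — running median, width 31 SNPs, constant end rule
   (matching R's `runmed(..., endrule="constant")`), applied per
   chromosome to F<sub>ST</sub>, π and the binned D track. H1/H12 are
   left unsmoothed by default: they are already 14-SNP window statistics,
   and a further 31-SNP median erases sweep-scale features. Missing
   values are set to 0 before smoothing. The smoothed set is
   configurable per statistic.
5. **Composite** — each smoothed track becomes fractional-rank p-values
   (average-on-ties; right tail for F<sub>ST</sub>/H1/H12, left tail for
   D/π; bounded in [1/(L+1), L/(L+1)] so logits are finite). A robust
   correlation matrix of the five tracks is estimated by FAST-MCD
   (α = 0.75, seeded; see below) and the composite is
   DCMS_l = Σ_t w_t·logit(1−p_lt) with w_t = 1/Σ_i|r_it|, the sum
   including i = t. With identity correlation this is the plain sum of
   logits; with all |r| = 1 it is the mean — a perfectly redundant panel
   counts once.
6. **Significance** — intercept-only Huber M-estimate (c = 1.345) of the
   DCMS location with scale fixed at 1.4826·MAD, iterated to relative
   tolerance 10⁻⁸; upper-tail normal p = 1 − Φ((DCMS−μ)/σ); BH step-up
   q-values (a Storey π₀ adjustment is available behind a flag, off by
   default). The fixed MAD scale makes the fit insensitive to the signal
   tail itself; the trade-off is that a right-skewed null yields some
   small q-values (see Limitations).
7. **Regions** — maximal runs of consecutive SNPs with q ≤ 0.1
   containing ≥ 2 consecutive SNPs with q < 0.05 (`core_min`
   configurable down to 1); the boundary SNP with q > 0.1 is exclusive.
   Region length is the member-SNP span (end − start + 1 bp); a single
   region reports SD 0.
8. **Annotation & enrichment** — gene rows from GTF, QTL records (trait
   and class attributes) from GFF3, 1-based inclusive coordinates,
   ≥ 1 bp intersection via interval trees. Enrichment per
   (trait, chromosome): observed = annotated QTLs of that trait on that
   chromosome; the null resamples, with replacement and within the same
   chromosome, as many database records as were annotated there, 1,000
   iterations; p = (1 + #{null ≥ obs})/(n_iter + 1) (add-one smoothing
   keeps p > 0); BH across all pairs, significance at FDR ≤ 0.05.
   Record-based sampling was chosen over position-based sampling; both
   views are defensible and the sampler is isolated if the alternative
   is ever wanted.

Determinism: one global seed derives all stage seeds through
`SeedSequence.spawn` with a fixed stage order (`config.STAGE_NAMES`), so
a stage rerun in isolation reproduces the full-run output, and two runs
with the same config and seed are byte-identical.

## FAST-MCD

The de-correlation weights use the minimum covariance determinant: the
h = ⌈0.75·L⌉ loci whose covariance has the smallest determinant,
located by random (p+1)-subsets, each improved by two concentration
steps, with the ten best candidates iterated to convergence. The
covariance is consistency-corrected (a scalar; it cancels in the
correlation) and converted to a correlation matrix. The subset count
defaults to 50,000; for a 5-column panel a few hundred random starts
already locate the same optimum, so the test suite and the acceptance
script use 500 — the estimator contract is unchanged, only the search
budget. A singular best subset (e.g. a statistic column that is
majority-constant, which happens when the smoothed F<sub>ST</sub> track
is mostly zero) falls back to the classical correlation with a logged
warning; zero-variance columns are then treated as uncorrelated.

## Synthetic data

The generator is a discrete-generation Wright–Fisher simulator on
standing variation: founder allele frequencies from Beta(0.5, 0.5)
truncated to [0.05, 0.95] (the U-shaped spectrum of an ascertained SNP
array, clear of the MAF filter), 200 diploids, 3 chromosomes × 2,000
SNPs at 25-kb spacing, crossover probability 10⁻³ per adjacent-SNP
interval per meiosis, chromosomes assorting independently. 200 burn-in
generations build LD and drift. A hard sweep is then planted: the
beneficial allele is assigned at frequency f₀ = 0.05 to the haplotypes
most similar to a random seed haplotype over the focal ±10 SNPs — a
single mutational origin old enough to have drifted to f₀ carries one
local background, and ±10 SNPs matches the expected unbroken ancestral
segment at these N and r — followed by 150 generations of additive
viability selection (weights 1, 1+s, 1+2s; s = 0.05), restarting with an
incremented seed if the allele is lost. Finally 150 individuals are
sampled and a founder/farm-born contrast is made by freezing 25% of
samples and breeding the remainder for 5 further generations (a few
herd generations, matching the decade-scale farm history the split
emulates). All truth (focal SNP, final frequency, labels) is recorded.

What it reproduces: array-like site-frequency spectra, realistic LD
decay, drift, genuine within-herd relatedness, a localized hard-sweep
footprint (elevated H12, depressed π, a fixed core), and tunable
two-group differentiation.

What it does not: **new mutations** (so post-sweep diversity never
recovers, and swept sites become monomorphic rather than rare-variant
rich), gene conversion, genotyping error, a realistic cattle demography
or recombination map. Two consequences matter for interpreting tests:

- A sweep that reaches fixation is *invisible at the swept SNPs
  themselves* after the MAF filter — they are monomorphic and removed —
  leaving a SNP desert plus partially-swept shoulders. Detection then
  rests on H1/H12 at the shoulders.
- Binned Tajima's D at an incomplete standing-variation sweep is pushed
  *positive* (hitchhikers sit at intermediate frequencies and no rare
  variants are regenerated), opposite to the classic post-sweep negative
  D of sequence data. In the composite, the left-tailed D therefore
  works against sweep detection in this regime. On real array data from
  an old, mutation-equilibrated sweep the left tail is the right choice;
  the simulator cannot produce that configuration.

Passing end-to-end tests on this generator therefore demonstrates the
pipeline's correctness and calibration, not field-realistic power: at
these desk-scale conditions (2N = 400, 350 generations of drift),
drift-born extremes of homozygosity and diversity are frequently as
large as the residual sweep signal, which is the known confounding of
selection scans in small populations. The per-statistic implementations
are validated separately against independent brute-force oracles to
1e-12, and neutral-spectrum calibration of D is tested directly.

## Numerical details

- Missing alleles use a −1 sentinel; all statistics exclude missing
  alleles from counts; missing statistic values are imputed to 0 only at
  the smoothing/ranking boundary.
- HWE p-values compare configuration probabilities with a 1e-12 relative
  slack so floating-point ties count as ties; the test is exact
  otherwise (validated against rational-arithmetic enumeration).
- Fractional ranks use average-on-ties; the two-sided option
  (2·min(left, right), capped at L/(L+1)) exists but is unused by the
  default five-statistic panel.
- The running median shrinks its window to the series length (next odd
  number below) when a chromosome is shorter than 31 SNPs.
- Region calling never merges across chromosomes; raising `boundary_q`
  can only widen coverage and raising `sig_q` can only add regions
  (property-tested).
- BED output is 0-based half-open; everything internal is 1-based
  inclusive.

## Known limitations

- The null distribution of DCMS is right-skewed and SNPs are correlated
  by LD and smoothing; with a normal-tail fit, a small fraction of
  neutral SNPs (≲ 1%) can reach q < 0.05 and form occasional false
  regions in a drifted population. This is a property of the composite
  construction itself, shared with the upstream method.
- PI_HAT from a few thousand LD-correlated SNPs has sampling noise of
  several hundredths; a hard 0.1 threshold is then indiscriminate in a
  uniformly related herd (hence pruning is opt-in).
- The enrichment bootstrap conditions on the annotated count per
  chromosome; traits absent from the database but observed get the
  minimal p = 1/(n_iter+1) rather than an error.
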