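# Methods

## The screen

The package targets the common two-group resequencing design: a "high" group
carrying a selected phenotype (e.g. high anthocyanin content) and a "none"
control group, genotyped at a shared set of bi-allelic SNPs, plus
non-replicated RNA-seq of both groups at three developmental time points.
Candidate genes come from two independent passes — loss of diversity in the
high group (selective sweeps) and consistent fold changes in expression —
which are reported separately, never intersected.

## SNP quality control

Sites are reduced in three stages, each evaluated on the same input counts
(so HWE-then-MAF and MAF-then-HWE retain identical sets):

* **bi-allelic screen** — exactly one single-nucleotide ALT, REF ≠ ALT, both
  in {A,C,G,T}; everything else is dropped and counted;
* **missingness** — sites with more than `max_missing` (default 0.5) of
  genotypes uncalled are dropped; called counts are used site-wise elsewhere;
* **Hardy–Weinberg filter** — 1-df chi-square goodness-of-fit of the pooled
  genotype counts against expectations at the pooled allele frequency,
  without continuity correction; sites are *kept* when p ≥ `hwe_alpha`
  (default 0.001). Monomorphic sites fit trivially (p = 1). An exact
  conditional test (enumeration over heterozygote counts at fixed allele
  counts) and a per-group mode are available behind config flags; at the
  default sample sizes the chi-square/exact gap is small (0.527 vs 0.564 at
  counts 3/4/3) and irrelevant at alpha 0.001.
* **MAF floor** — pooled minor-allele frequency ≥ `maf_min` (default 0.1),
  non-strict at the boundary.

Both keep-conditions are deliberately read as retention rules; the filter
sentence they derive from is ambiguous in the source domain literature, and
the non-strict keep is the standard reading for rice diversity panels.

Transitions are A↔G and C↔T; the other four unordered pairs are
transversions. The Ts/Tv ratio is reported to three decimals in summaries; a
set without transversions reports NA with counts intact.

## Window statistics

Windows are half-open 0-based intervals starting at 0, step, 2·step, …
(emitted while start < chromosome length, end clipped). `step == size` gives
the non-overlapping tiling (10/50/100/500-kb analyses, 5-kb export tracks);
the default scan uses 100-kb windows with a 20-kb step. Terminal short
windows are scored but flagged; a config option excludes them.

* **π** — per site, the unbiased mean pairwise difference
  2·p·(1−p)·n/(n−1) over the group's n called alleles; per window, the sum
  over in-window SNPs divided by the window span in bp. The per-bp
  denominator is what makes the candidate ceiling π ≤ 0.005 meaningful on
  kb-scale windows; a per-SNP denominator is not offered.
* **ROD** — 1 − π_high/π_none; NA when the control is monomorphic in the
  window (the contrast carries no information there), and NA windows are
  excluded from the ROD quantile.
* **Hp/ZHp** — Hp sums major and minor allele counts over the window's SNPs
  (high group by default; pooled behind a flag) and ZHp standardizes Hp with
  the genome-wide mean and population sd over scored windows. Windows under
  the `min_snps_per_window` floor (default 30, applied to the sliding scan)
  are excluded from the moments and can never be hits.
* **FST** — Hudson's two-population estimator, numerator and denominator
  summed separately over in-window SNPs before dividing (the
  ratio-of-sums combination); sites with fewer than two called alleles in
  either group are skipped. Slightly negative windowed values are expected
  under no differentiation at finite sample size.

## Region calling and gene overlap

A scored window is a hit when ZHp ≤ `zhp_threshold` (default −1.5) **or**
when ROD is positive, at or above the empirical (1 − alpha) quantile of
defined ROD values (default alpha 0.01), and π_high ≤ `pi_max_for_candidate`
(default 0.005/bp). The two rules are combined by OR because they flag the
same signal from different statistics and are applied as separate passes in
the design this implements; the empirical quantile stands in for a
significance level because no parametric null for windowed ROD is assumed.
Overlapping or bookended hit windows merge into maximal regions; a region's
ZHp is the minimum over member windows, and genes overlapping a region by
≥ 1 bp are reported with their in-gene SNP count and that region ZHp. Gene
inclusion is region-level on purpose: a gene's own ZHp may sit slightly
above the window threshold while its region passes.

## Expression screen

Group summarization is the arithmetic mean of FPKM over accessions within
group and time point (median behind a flag); ratios are
(mean_high + c)/(mean_none + c) with pseudocount c = 0.01 so fully silenced
transcripts yield finite down-ratios (0.01-scale) rather than zeros. A time
point passes at ratio ≥ 2 (up) or ≤ 0.5 (down), boundaries inclusive; stages
require ≥ 1, ≥ 2 or all 3 passing time points with a consistent direction
(strict by default, relaxable). Regulation is `up`/`down` only when all time
points agree, so the calls are exclusive by construction. Transcripts missing
any (group, time point) cell are excluded and listed in the result's
`attrs["excluded"]`.

Enrichment takes a generic gene → term membership table (no ontology
hierarchy): per term, the one-sided Fisher's exact p is the upper
hypergeometric tail P[X ≥ k]. The permutation FDR shuffles the selection
labels over the universe `n_randomizations` times (default 100) and reports,
per term, the mean count of null p-values at or below the observed p divided
by the observed count of terms at that level, clipped to [0, 1] — a
plug-in estimate of expected false discoveries over observed discoveries at
each term's own threshold. Degenerate case: with a single term the
denominator is 1 and the FDR is just the permutation p-value.

## Synthetic data

The generator draws, per chromosome, unique sorted positions and a per-site
minor-allele frequency from Uniform(0.05, 0.5); both groups share the site
frequency, and diploid genotypes are drawn independently per sample under
Hardy–Weinberg proportions at the group frequency. Inside a planted sweep
region the high group's frequency is multiplied by (1 − diversity_reduction),
so a reduction of 1 leaves the high group homozygous reference (π_high = 0,
ROD = 1). REF/ALT bases are drawn with a 0.7 transition share so Ts/Tv
summaries land near the ~2.3 typical of genuine SNP sets. Defaults — 3
chromosomes × 2 Mb, 8 high / 9 none accessions, 20,000 SNPs per chromosome —
put background diversity near 0.004/bp, the scale at which the π ≤ 0.005
candidate ceiling operates.

Deliberately not modelled: linkage, recombination, demography and
sequencing-read noise. Planted sweeps are frequency rescalings of
independent sites, not coalescent sweeps, so recovery results show that the
window statistics and calling rules respond correctly to reduced diversity —
not that the thresholds are calibrated for any particular demographic
history. Time points are exchangeable labels; no temporal trend is simulated.

Expression: lognormal per-transcript baselines shared by both groups
(log-mean 2.5, log-sd 1.0), planted DE transcripts multiply (up) or divide
(down) the high group by a fold ≥ 2 at every time point, and observations
carry mean-one multiplicative lognormal noise with coefficient of variation
`noise_cv` (default 0.2, a plausible between-accession spread for FPKM).
Group sizes default to the 8 high / 2 none RNA-seq layout. Values are
floored at 10⁻³ so expressed transcripts never emit exact zeros; zero/ratio
edge handling is exercised with hand-built fixtures instead. Seeds are
mandatory everywhere; identical seeds give byte-identical files.

## Numerical and interface choices

* Internal coordinates are 0-based half-open; VCF and GFF3 (1-based) convert
  at the read/write boundary, BED output stays 0-based half-open, and TSV
  reports print 1-based inclusive coordinates with the convention stated in
  a header comment.
* ZHp uses the population (ddof 0) standard deviation; an all-equal-Hp scan
  raises rather than silently emitting zeros.
* The ROD quantile uses linear interpolation (`numpy.quantile` default) over
  defined, scored-window ROD values.
* Chromosome names pass through verbatim; no "chr" normalization.
* Problem sizes in the test suite and acceptance script (1–6 Mb genomes,
  10–20 k SNPs per chromosome, 20 replicates, 1000-transcript expression
  panels) were chosen as the smallest sizes at which the Monte-Carlo checks
  (recovery ≥ 95%, null calibration ≈ 1%) are stable across seeds.

## Limitations

Counts from any real screen (numbers of raw/filtered SNPs, staged DEG
counts) depend on the underlying accessions and are not reproduced by the
synthetic generator — only rule structure and operating characteristics are.
The HWE chi-square is anti-conservative at very small sample sizes; use the
exact flag below ~20 genotypes if the alpha matters. The FST track is
descriptive; no significance is attached to it. Fisher enrichment treats
terms independently (no hierarchy, no overlap correction between terms).
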