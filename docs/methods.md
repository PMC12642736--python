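# Methods

## Scope and data model

`txrank` starts at assigned isoform counts: one row per (isoform, gene,
individual, condition, haplotype) with a raw full-length-read count.
Alignment, isoform collapse, classification, and read phasing are upstream
concerns; whatever tool produced the counts, the table contract is the
same. Duplicate keys (e.g. multiple SMRT cells or lanes) are summed during
validation, each isoform must map to exactly one gene cohort-wide, and the
matrix is completed densely with zeros so that leave-one-out statistics see
every individual for every feature. Antisense and fusion "genes" are
ordinary `gene_id`s supplied by the input.

## Normalization

TPM is the count proportion of the (individual, condition) library scaled
to 10⁶. No transcript-length correction is applied: each full-length
non-chimeric read is one transcript observation, so the count proportion
already estimates the transcript proportion. The denominator combines both
haplotypes and unphased reads; haplotype-resolved values are kept as raw
untreated counts only, because the allelic-imbalance statistic consumes
counts, not TPM. Gene TPM is the sum of isoform TPM. An all-zero library
yields TPM 0 with a logged warning rather than an error.

Libraries deeper than the configured threshold (default 7,000,000 reads)
are thinned read-by-read with probability `p = target / n_reads` (target
5,000,000, `p` rounded to six decimals), so retained counts are binomial
with mean `n·p`. The threshold is inclusive: a library at exactly the
threshold is untouched. Thinning is applied as binomial sampling of the
aggregated counts, which is distributionally identical to per-read
retention; per-library seeds derive deterministically from the run seed.

## Test statistics

All logarithms are base 2 and all statistics are signed so the pattern of
interest is positive; each is exactly zero when the index value equals its
comparison value. "Others" means all individuals except the index one; ties
in min/max are resolved by value, so no index bookkeeping is needed.

Design choices worth calling out:

* **Rarity bins.** Bin membership for the rare-steady-state statistic is
  decided by the untreated sample's isoform proportions alone and shared
  across conditions. When a gene has zero untreated reads, all its isoforms
  are bin 1 (proportion defined as 0) — this is precisely what lets a fully
  NMD-degraded gene score: its CHX-only reads all land in the rare bin.
* **Allelic-imbalance filters.** The phased-fraction denominator is the
  feature's total untreated reads (phased + unphased). Features failing
  either filter are *excluded* from the test, not scored 0, so they can
  neither dilute the percentile threshold nor displace genuine outliers.
  Both filters are applied at the level of the feature being tested (gene
  or isoform).
* **Roster.** Gene level runs all six tests; isoform level omits the
  rare-steady-state statistic (it is intrinsically a within-gene contrast).
  The NMD statistic alone contrasts the two conditions; both
  gain-of-expression variants are computed independently.

## Outlier scoring and ranking

The per-feature cohort of statistic values is converted to a z-score using
the median of the other individuals and the sample standard deviation
(n − 1 denominator) over *all* individuals, with z = 0 when that standard
deviation is zero. Features with undefined statistics are excluded before
anything else.

The retention threshold is the per-individual percentile (default 99.5) of
that individual's z distribution for the test, computed with linear
interpolation on the empirical distribution; features strictly above it are
retained. This pairing of quantile rule and strict inequality reproduces
the worked example "1,000 distinct z-scores → top 5 retained" and is pinned
by a unit test; with all z equal, nothing is retained. Only the upper tail
is filtered: every statistic is oriented so that its alteration of interest
is positive, so negative extremes are the uninteresting direction by
construction. Retained features are ranked by descending statistic with
ties broken by feature identifier, giving gapless ranks 1..k and
deterministic output.

## Synthetic cohorts

The generator emulates the cohort design the method assumes, not reads or
alignments. Per cohort: gene expression weights are log-normal (σ = 1.5 in
natural log, spanning the several orders of magnitude seen in real
libraries), isoform shares within a gene are Dirichlet(α = 2), and each
(isoform, individual) gets a log-normal biological factor shared between
conditions plus a smaller per-condition factor, with Poisson sampling at
the library depth. The shared biological factor makes the treated/untreated
contrast null in expectation for unspiked features; the condition factor
(CV 5%) gives the NMD statistic a realistic null spread. Reads are split
H1 / H2 / unphased with a phased fraction of 0.8, approximating imperfect
propagation of ~92.5% variant phasing to reads.

Defaults are 11 individuals, 300 genes (~900 isoforms), and 5,000,000
expected reads per condition. Depth is kept at the study scale while the
transcriptome is reduced: the statistics' +1-TPM pseudocounts implicitly
calibrate TPM units against a multi-million-read library, so shrinking
depth (rather than feature count) inflates Poisson noise in TPM units and
changes the null behavior of the ratio statistics. Since counts are drawn
per feature, depth costs nothing computationally; the reduced feature count
is what keeps a full pipeline run at about one second.

The biological CV default of 10% reflects the low inter-individual
variability of cultured fibroblast lines — the reason fibroblasts are the
tissue of choice for this assay. Real tissues, and individual genes with
variable expression, can be far noisier; spike-recovery results on these
cohorts therefore demonstrate the machinery under the design's intended
conditions, not performance floors for arbitrary real data. The generator
also does not simulate isoform-caller behavior (lumping/splitting of novel
isoforms), mapping artifacts, or batch structure.

Spike kinds map one-to-one onto the alteration classes the tests target;
default effect sizes are a 0.9 degradation fraction (NMD), 8-fold
expression change applied in cis to one haplotype (loss/gain), a fully
monoallelic haplotype skew at constant total (imbalance), and a novel
isoform at 30% of its gene's treated expression but 0.3% untreated (rare
steady state). The loss spike therefore reduces total expression to
(1 + 1/8)/2 ≈ 0.56 of baseline — a heterozygous-lesion-sized effect, which
is the hardest of the five classes to recover and behaves accordingly in
the titration.

## Problem sizes used in tests and the acceptance script

Recovery benchmarks use 100 replicates (test suite) or 40 replicates
(acceptance script) of the default 11-individual cohort; null calibration
uses 50 / 30 spike-free cohorts, pooling the six gene-level tests; the
robustness titration runs cohorts of 4, 11, and 31 individuals at depths of
50k, 500k, and 5M reads with 12 replicates per cell and asserts trends
(stability from 31 to 11, degradation below 11, monotone recovery in
depth), not exact fractions. These sizes keep the whole suite at a few
minutes on one CPU while leaving the trend assertions comfortably clear of
replicate noise.

## Numerical and degenerate-input conventions

* Statistics are pure functions of finite inputs; no clipping is applied.
  `log₂(H1+H2)` in the imbalance statistic is safe because the phased-read
  filter guarantees a positive argument (a guard handles a zero-read corner
  when the filter is disabled).
* z-scores with fewer than two scored individuals are undefined (NaN) and
  excluded; phased counts exceeding the untreated total raise a consistency
  error rather than being repaired.
* All randomness flows through `numpy.random.SeedSequence` spawning, so
  every artifact (cohort TSVs, ranked outputs, manifests) is byte-identical
  across reruns with the same seed, and structure (gene/isoform identities)
  is reproducible independently of noise draws.
* Method constants (percentile 99.5; phased-read and phased-fraction
  filters 10 and 10%; rarity threshold 1%; depth target/threshold 5M/7M)
  live once in `txrank.config` and are plumbed through as parameters.

## Known limitations

* The percentile filter admits only positive outliers; an alteration that
  manifests as an extreme *negative* statistic under some test is by design
  captured by the complementary test (e.g. loss rather than gain), not by
  the lower tail.
* Gene-level aggregation is a plain sum over the input's isoform → gene
  map; mis-assigned isoforms (caller lumping/splitting) propagate directly
  into gene statistics, and no attempt is made to model or correct this.
* With very small cohorts the z-score saturates (the index value dominates
  the cohort standard deviation), so discrimination collapses regardless of
  effect size; the titration quantifies this rather than working around it.
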