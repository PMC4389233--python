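# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Coordinates and interval algebra

All internal coordinates are 0-based half-open (BED convention); GTF, the
one 1-based inclusive format, is converted at the file boundary in both
directions. Merge, subtract and intersect are position-set operations:
touching intervals (`a.end == b.start`) merge, because a zero-length gap is
no gap when intervals describe sets of blacklisted or state-marked
positions. Chromosome names are compared as exact strings; an optional
`normalize_chroms` flag maps `1 ↔ chr1` at read time and is off by default.
The whole algebra is validated against a per-base bitmap oracle on a toy
chromosome, which is the authoritative semantics.

## Enhancer discovery

The filter chain is: (1) per-base union across cell lines of segments whose
chromatin state is in `enhancer_state_ids` (default {4, 5, 6, 7}, the
enhancer classes of the integer-coded segmentation this models);
(2) subtraction of the TSS blacklist — the union of symmetric windows
`[tss − flank, tss + flank + 1)` with flank 1000 bp, a 2,001-bp window
centred on the TSS base; (3) removal of regions overlapped by annotated
transcripts on both strands, whose nascent signal would look bidirectional
for trivial reasons; (4) the requirement of ≥ 1 p300 and ≥ 1 Pol2 peak
overlapping the region by ≥ 1 bp; (5) extension by 1 kb and per-sample,
per-strand counting of read 5' ends; (6) the bidirectionality filter.

Open choices, fixed as follows:

- **Blacklist granularity.** Blacklisted *positions* are trimmed out of
  regions (fragments survive) rather than dropping whole regions; a
  `blacklist_mode="region"` option provides the stricter reading. Position
  granularity was chosen because the blacklist is defined as a set of
  excluded positions, not a region predicate.
- **"Detectable transcription".** The weakest defensible reading: ≥ 1 read
  per strand pooled across all samples, exposed as
  `min_reads_per_strand`.
- **Counting rule.** A read is assigned by its 5'-end position (one
  assignment point per read), which tracks polymerase position in run-on
  data and avoids read-length bias; a read is counted once per region whose
  extended window contains that position.
- The blacklist and cofactor steps are pure region filters, so their
  relative order cannot change the result; the suite asserts this on
  simulated data.

Transcript collapsing for omnibus annotations merges same-strand
overlapping transcripts into one locus whose exon set is the per-base union
of member exons; opposite strands never merge.

## Exact NB test

The differential test is an exact conditional test in the edgeR tradition,
deliberately simplified to an enumerable contract:

1. Scale each sample's count by `common / lib`, where `common` is the
   geometric mean of all library sizes; sum per condition and round to the
   nearest integer.
2. Under the null, each scaled sample shares mean `m = n / (n_A + n_B)`
   where `n` is the pooled total; a group sum of `n_g` i.i.d. NB(m, φ)
   draws is NB with mean `n_g·m` and size `n_g/φ` (variance
   μ + φμ²/n_g).
3. The conditional law of the group-A sum given `n` is the normalized
   product of the two pmfs; the two-sided p-value is the sum of conditional
   probabilities of every split as likely or less likely than the observed
   one (no doubling). φ = 0 is the Poisson limit, where the conditional law
   is exactly Binomial(n, n_A/(n_A+n_B)).

This replaces TMM normalization and quantile-adjusted CML with
geometric-mean scaling and a method-of-moments common dispersion
(φ̂ = Σ(v−m)/Σm² over replicated conditions, floored at 0; a configured
fallback with a warning when nothing is replicated). The exact-test
semantics — not a particular normalization — is the tested contract: the
implementation must agree with an independent lgamma-based enumeration over
all splits, to relative 1e-9. Tagwise/trended dispersion and the GLM
framework are explicitly out of scope.

Library sizes may come from the full library rather than the tested
features. This matters: on a small feature panel, per-panel column sums are
dominated by the strongest responders and induce a composition artifact
(everything else appears repressed).

**Regulation classing.** Strands are tested separately, but the BH step-up
is computed jointly over the concatenated plus/minus p-value vector (one
correction over 2m tests). An enhancer is *regulated* when either strand
passes the FDR threshold (default 0.01, configurable — the published
threshold is stated for genes and assumed for enhancers), *induced* or
*repressed* by the sign of the passing strand's log-fold-change, and
*discordant* (counted separately) when both signs pass. The joint
correction keeps the enhancer-level null call rate at or below q, which the
null-calibration test relies on; correcting each strand separately would
let the union rate drift toward 2q.

## p53 classification

- **Peak filter.** Strictly-below thresholds are discarded: a peak at
  exactly fold 3.0 and −log10 q 2.0 survives.
- **"Within 1 kb".** Edge-to-edge gap ≤ 1000 bp, inclusive, with overlap
  counting as gap 0 — the most permissive literal reading; the window is a
  parameter. Whether distance should instead be measured summit-to-region
  is unresolved in the source material; edge-to-edge was chosen because
  summits are optional in peak files.
- **Midpoint of bidirectional transcription.** Not defined in the source
  material; this package defines it as the position `p` minimizing the
  misplaced-read objective `#{plus 5' < p} + #{minus 5' ≥ p}` over the
  extended region, ties to the smallest `p`, computed on the pooled treated
  replicates. The definition is isolated behind one function so
  density-weighted or max-gap alternatives can be swapped; a region without
  reads on both strands raises an explicit error.
- **Drop-off profile.** Per enhancer, both strands are oriented downstream
  (plus: `pos − mid`; minus: `mid − 1 − pos`), binned to `max_bp`
  (default 2000 in 100-bp bins), normalized to unit mass *per enhancer*
  before the per-bin median across enhancers of a class — region-level
  normalization first, then the median, so deep enhancers do not dominate.
  The q75 distance is the upper edge of the first bin where the cumulative
  density reaches 0.75.
- **Nearest-gene distances** are edge-to-edge gaps to gene bodies by
  default (0 when overlapping); a TSS anchor is provided as an option.
- **Motif windows** are `[mid − 100, mid + 100)` (200 bp), truncated with a
  warning at chromosome ends; backgrounds are bidirectional enhancers with
  differential-expression FDR ≥ 0.75 on both strands, additionally free of
  any p53 peak within 1 kb for the FER background.

## ChIRP reconciliation

Pool peaks are filtered at −log10 q ≥ 5 and enrichment ≥ 4 (inclusive).
Every overlapping odd/even pair is a merge candidate evaluated over the
union span of the two peaks: per-base coverage Pearson r ≥ 0.2 and ≥ 25
reads in each pool. Choices:

- The read floor is evaluated over the *union span* — the region actually
  being merged — with coverage defined as 5'-end counts per base, so the
  coverage sum over a span is the read count on it.
- Zero-variance coverage on either pool makes the correlation undefined and
  rejects the pair, with a logged reason.
- Merging is transitive through shared source peaks (one odd peak passing
  with two even peaks yields a single site); since such pairs overlap
  through the shared peak, merging union spans realizes the transitivity.
- Contaminant removal is any-overlap: a partial overlap with a blacklist
  interval removes the site.

State enrichment assigns each site to the chromatin state covering its
midpoint (keeping observed counts integral); expected counts are
`n · state_bp / total_bp` and the p-value is the binomial upper tail. A
bp-apportioned mode was considered and rejected for making the observed
count non-integral. Enrichment of induced enhancers among bound ones is the
hypergeometric upper tail `P(X ≥ overlap)` with the candidate-enhancer set
as population.

## Methylation association

The methylated fraction of a clone matrix excludes missing entries from the
denominator; the binary call threshold (default 0.5) is inclusive. The
association test is the Pearson chi-square on the 2×2 table **without**
Yates continuity correction: on the published 135-cell-line table
([[29, 30], [19, 57]]) the uncorrected statistic gives p = 0.0037 (prints
0.004) while the corrected one gives ≈ 0.006, which fixes the test variant
the published value implies. Percentages are rounded half away from zero;
the published patient table contains one row (1/6 printed as 16) that is
inconsistent with any single convention, so a truncation convention is also
exposed and that row is excluded from assertions. The
expression-vs-methylation comparison is a two-sided Mann–Whitney U with the
rank-biserial correlation as the signed effect size (negative = silencing).

## The synthetic-data generator

The generator emulates the statistical structure of the study's inputs on
a toy genome, with every feature placed in a private 25-kb block so that
planted loci never interact through 1-kb windows.

Reference conditions (the defaults, used by the test suite and the
acceptance script): two 5-Mb chromosomes; 200 enhancers, 26% induced and
10% repressed at 8-fold (so ~72% of the regulated set is induced, the
signature of a mostly activating program); half of the induced enhancers
p53-bound; 3 + 3 replicates with baseline NB mean 100 reads per strand per
sample and dispersion 0.05; 3 cell lines covering each enhancer with
probability 0.7 (coverage in at least one line enforced); 40 lncRNA binding
sites of which 60% sit in the designated strong-enhancer state (id 4),
preferentially (3:1) on induced enhancers; 8 ChIRP decoys (anti-correlated
or under-sequenced) and 4 plasmid contaminants.

What is emulated: state-marked enhancers with p300/Pol2 peaks; bidirectional
5'-end reads around a planted midpoint with exponential drop-off (tighter
for bound enhancers, 250 vs 600 bp scale, so drop-off orderings are
testable); NB count noise with condition-dependent means; sub-threshold p53
and ChIRP peaks that must be removed by the filters; decoys violating
exactly one discovery filter each; correlated bump-shaped dual-pool ChIRP
coverage; and a bisulfite-clone cohort with TP53-dependent methylation
propensity (10 clones per sample, entry rates 0.85/0.08, 2% missing).

What is *not* emulated — and therefore what passing tests do not show about
real data: sequence content (GC bias, mappability), fragment-level
coverage shape, overdispersion heterogeneity across loci (the common-φ
model is exactly true here), enhancers overlapping genes or each other,
library composition effects (the generator reports true sequencing depths
as library sizes; real analyses must supply full-library totals), and any
spatial correlation between enhancers and their target genes.

Reads are represented directly as stranded 5'-end positions (BED6 with
1-bp records), skipping FASTQ and alignment, since counting operates on
alignments. Everything is a deterministic function of the seed;
re-simulating and re-writing with the same config is byte-identical.

## Problem sizes and calibration

The test suite and acceptance script run the full pipeline at the reference
conditions above (~200 enhancers on 10 Mb, a couple of seconds per
simulation) and the null calibration on 20 seeds of a compact no-effect
configuration (120 enhancers on 5 Mb). These sizes give the planted-truth
checks (≥ 90% recovery of induced enhancers at FDR 0.01, false-discovery
proportion ≤ 0.05, exact BER/FER agreement, ChIRP site recovery/rejection,
hypergeometric P < 0.01) comfortable Monte-Carlo margins, which were
verified across independent seeds before being frozen.

## Known limitations

- The exact test's rounding of scaled group sums makes p-values piecewise
  constant in library-size ratios; for very small counts this is visible.
- The conditional NB law is computed by direct enumeration over the pooled
  total, which is O(n) per feature (cached per total); extremely deep
  features (totals ≫ 10⁶) would want a saddlepoint approximation instead.
- `reconcile_pools` is quadratic in peaks per chromosome pair-wise overlap
  scanning; adequate for peak sets in the thousands, not millions.
- The midpoint definition is one reasonable choice among several; drop-off
  distances shift by a few bins under alternatives.
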