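# Methods

`chromfusion` implements the computational core of a fusion-oncoprotein
chromatin study: deciding which genome bins are enriched in a ChIP
experiment, assembling replicate peak calls into a consensus
architecture, scoring peaks on a common scale, contrasting paired
conditions, and wiring chromatin loops to target genes. Every stage is
exercisable on synthetic fixtures with planted ground truth; this note
records the models, the parameters that matter, and the design choices
made where the design was genuinely open.

## Bin-level enrichment: quantile-stratified Z-scores

The genome is split into fixed 400-bp bins and each retained read is
assigned to the bin containing its 5′ position. Per bin the IP and the
Input sample receive a score `log2(count + pseudo)` (pseudo-count 1),
and the log2 fold change is `score_IP − score_Input`. Bins are ranked
by the mean score `(IP + Input)/2` and split into `n_quantiles`
(default 10) equally sized abundance strata; within each stratum the
fold change is standardized with the stratum's mean and sample standard
deviation (ddof = 1), converted to an upper-tail standard-normal
p-value, and Benjamini–Hochberg adjusted within the stratum. A bin is
enriched when its FDR falls below 0.001.

The stratification exists because the sampling noise of a count
log-ratio depends strongly on abundance: a single genome-wide standard
deviation would be dominated by low-count bins and lose all power at
high counts. One-sided (upper-tail) p-values are used because the
statistic targets enrichment; depletion is not a call this method
makes.

Numerical choices:

* quantile membership is by rank with stable (genomic-order) tie
  breaking, so quantile sizes differ by at most one and results are
  deterministic;
* a stratum whose fold changes have zero spread yields Z = 0 for every
  bin in it — identical bins carry no evidence;
* BH adjustment is per-stratum by default; a genome-wide mode
  (`bh_scope="global"`) is exposed because either reading of
  "FDR within each quantile" is defensible;
* the pseudo-count default is 1, consistent with the `+1` the peak
  score formula uses explicitly.

Externally produced candidate peaks (e.g. a model-based peak caller's
output, which this package deliberately does not re-implement) are then
*gated*: a candidate survives iff it overlaps at least 1 bp of an
enriched bin. Overlap is always ≥ 1 bp under 0-based half-open
coordinates, everywhere in the package.

## Consensus architecture and annotation

Replicate peak sets are pooled and merged whenever two intervals
overlap or lie within 150 bp of each other (transitively); a merged
region enters the consensus only if it overlaps a peak in *every*
replicate experiment (a configurable `min_sets` relaxation exists). Two
antibody consensus sets — one against the fusion-specific terminus, one
against the partner-protein terminus — are partitioned by overlap into
fusion-bound sites and single-factor sites.

Peaks are labeled `TSS` when they overlap any gene's `TSS ± 1 kb`
window (closed at both displayed ends, implemented half-open as
`[tss−1000, tss+1001)`), or when promoter-mark (H3K4me3) enriched
regions support them in all supplied replicate sets; everything else is
`Distal`, subdivided into intragenic/intergenic by ≥ 1 bp gene-body
overlap. Reported percentages use round-half-away-from-zero so printed
integer tables are reproduced exactly.

## Peak scores

For a peak of width `w`, raw read counts are scaled to a 20 M-read
library and a 500-bp width: `norm = raw × (2e7/libsize) × (500/w)`;
the score is `log2(norm_IP + 1) − log2(norm_Input + 1)`. Peaks narrower
than 500 bp are up-scaled by the same formula — the scaling target is a
normalization convention, not a special case. Scores of peaks whose IP
read count falls below the dataset's mean Input peak count are floored
to 0 (no credible signal above chromatin background); flooring uses raw
counts by default, with a normalized-count switch for designs where IP
and Input depths differ deliberately. Flooring precedes replicate
averaging. Cross-sample comparisons use classical rank-based quantile
normalization (ties receive the average of the row means their ranks
span) with a strict `> 3.5` retention cutoff, and Pearson correlations
with t-distribution p-values.

## Condition contrasts

Paired-condition peak sets are pooled (±150 bp) into a union with
per-condition presence tags. Three classifiers operate on such unions:

* **site categories** — a reference site lacking the partner factor in
  both conditions (`NoATF1`), gaining it only in the treated condition
  (`DeNovo`), or carrying it in both with a score increase
  (`PreExisting`; without increase, `Dropped`). The categories
  partition the input;
* **de-novo activation** — fewer than 5 raw reads in control *and* a
  pseudo-counted, library-normalized fold change above 4. The raw-count
  gate follows the stated rule; the fold change is computed on
  depth-normalized counts by default (a raw-count switch exists since
  the original convention is not recorded);
* **differential peaks** — score difference strictly above +2 / below
  −2 log2 units.

All thresholds are strict inequalities, matching the `<`/`>` operators
of the rules they implement.

## Loop connectivity

Loops are cis anchor pairs with interaction counts; inter-chromosomal
pairs are rejected on input with a count report, anchors are
canonicalized to genome order, and loop length is the
midpoint-to-midpoint distance. The pipeline keeps loops with counts
strictly greater than 5, marks a loop fusion-associated (EA) when
either anchor overlaps a fusion-binding site, and calls a gene a target
when its promoter (`TSS ± 1 kb`) overlaps an anchor — a target *of the
peak set* when additionally an anchor of the same loop overlaps a peak.

Paired conditions are normalized with median-of-ratios size factors
over loops nonzero in both conditions (geometric-mean reference);
normalized counts are raw counts divided by the factor. With two
samples, scaling one condition by `c` moves the factor *ratio* by `c`
and leaves every normalized fold change invariant — the property the
2-fold differential call depends on. The differential call itself uses
pseudo-counted ratios `(norm + 1)` to stabilize zeros. Per-anchor loop
burden (loop count, summed interaction counts) is summarized per class
with medians, quartiles, and 1.5×IQR whiskers, and compared with a
Welch (unequal-variance) two-sided t-test; two degenerate identical
classes report p = 1 by convention, and classes with fewer than two
anchors skip the test with an explanatory reason. Target genes are
intersected with an externally fitted differential-expression table at
adjusted p < 0.05 and linear fold change > 1.5 (`|log2FC| > log2 1.5`),
split by sign, with genes absent from the table counted as untested.

## The synthetic fixture generator

The generator emulates the statistical structure of the study's inputs
at desk scale, with a machine-readable truth object as the test oracle.

* **Genome** — 4 chromosomes, mean 3 Mb (12 Mb total, 30 000 bins of
  400 bp); lengths take evenly spaced factors in [0.8, 1.2] of the
  mean, permuted by the seed and rounded to bin multiples.
* **Tracks** — Input bins are Poisson with a uniform background rate;
  IP bins are Poisson with the same rate times the planted fold inside
  enriched regions (optionally times a per-condition multiplier). An
  optional gamma-Poisson dispersion parameter provides negative-
  binomial stress tests; Poisson is the default because it is the
  simplest model matching count data.
* **Default study conditions** — background 5 expected IP reads per
  bin, ten planted 800-bp regions at 8-fold enrichment (≈0.07 % of
  bins), and a deep pooled Input at 10× the IP depth. The deep Input
  mirrors standard ChIP-seq practice of sequencing one Input control
  deeply and sharing it across many IPs, and it is statistically
  load-bearing: at equal depth the Input's own Poisson noise spreads
  the planted log2 fold changes by ≈0.6 units, which no within-stratum
  standardization can recover at FDR 0.001. With these conditions the
  caller flags ≈95 % of planted bins (measured across seeds) with a
  null false-positive rate indistinguishable from zero.
* **Peak calls** — each replicate contains each planted region with
  probability `1 − dropout` (default 0.05), boundaries jittered by
  Gaussian noise (default SD 25 bp), clipped to the genome.
* **Loops** — planted loops connect a 5-kb anchor on a planted region
  to a 5-kb anchor on a dedicated target gene's promoter 100–300 kb
  away (counts Poisson around 50, comfortably above the count-5
  filter); noise loops connect random anchor pairs (counts Poisson
  around 3) that avoid planted regions and promoters, so the planted
  wiring is exactly the set of true (loop → gene) links and the
  zero-false-target check is well defined. Target promoters are
  rejection-sampled clear of all other planted features. The 5-kb
  anchor width reflects restriction-fragment-scale resolution and is
  configurable.
* **Genes** — one dedicated target gene per looped region, a fifth of
  regions placed at gene promoters (promoter-bound sites), and
  scattered background genes whose promoters never overlap planted
  anchors.

What the generator does **not** model: mappability and blacklist
structure, GC and fragment-length biases, correlated replicate noise,
fragment-level contact matrices, or trans interactions. Passing tests
therefore demonstrate the correctness and calibration of the
*procedures* under their stated assumptions, not performance on real
sequencing data.

## Pipeline and problem sizes

The orchestrated demo (simulate → enrichment → gating → consensus →
fusion partition → annotation → scoring → loops → report) runs the
default fixture in a few seconds on one CPU and is byte-reproducible
for a fixed seed (all stage seeds derive from the config seed). The
statistical checks in the test-suite and the acceptance script use
30 000-bin genomes with 10–20 seeds per measurement — sizes chosen so
that Poisson means are estimated to a few percent while the whole suite
stays interactive.

## Known limitations

* The enrichment caller's per-bin power depends on the Input depth
  ratio (see above); analyses with shallow Inputs should expect the
  region-level gate (any flagged bin in a peak) to carry more of the
  sensitivity than the per-bin calls.
* The input-floor rule compares raw counts across samples and silently
  assumes comparable IP/Input depths; the normalized-count switch
  should be used otherwise.
* Quantile normalization with heavy ties does not leave columns with
  identical sorted values (tied entries receive averaged row means);
  this is the conventional tie policy, not a defect.
* `loop_stats` reports NaN t-statistics when both classes have zero
  variance but different means are absent — scipy's convention is kept
  except for the exactly-identical case, which reports p = 1.
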