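# chromfusion

Analysis toolkit for the chromatin biology of fusion oncoproteins —
chimeric transcription factors (such as EWSR1–ATF1 in clear cell
sarcoma) that bind distal regulatory elements, recruit their wild-type
partner factor, activate enhancers de novo, and rewire 3D chromatin
loops toward oncogenic target genes. The package is written for
computational biologists who need the bespoke statistics of this kind
of study as tested, reusable components rather than one-off scripts:

* **bin enrichment** — a quantile-stratified Z-score caller for ChIP-seq
  IP/Input bin counts, used to gate externally produced candidate peaks;
* **peak architecture** — ±150 bp merging, all-replicates consensus,
  fusion vs single-factor partition, TSS/Distal and
  intragenic/intergenic annotation;
* **peak scoring** — `log2(IP+1) − log2(Input+1)` on counts normalized
  to 20 M reads and 500 bp width, input-floored, replicate-averaged,
  quantile-normalized across samples, correlated across assays;
* **chromatin dynamics** — No-partner / De-novo / Pre-existing site
  categories, de-novo activation calls (< 5 control reads, fold > 4),
  and ±2 log2 differential peaks between conditions;
* **loop connectivity** — count filtering (> 5), fusion-association of
  loops by anchor overlap, promoter(±1 kb)–anchor target-gene
  assignment, median-of-ratios normalization, 2-fold differential
  loops, per-anchor burden statistics with Welch t-tests, and
  intersection with a differential-expression table;
* **synthetic fixtures** — a generator that plants enriched regions,
  replicate peak calls, condition effects, and promoter-wired loops
  with a machine-readable truth object, so every stage is testable
  end-to-end without any download.

## The core statistic

For 400-bp genome bins with IP and Input counts, each bin gets scores
`log2(count + 1)`; bins are split into abundance quantiles on
`(IP + Input)/2`, and within each quantile the fold change
`log2(IP) − log2(Input)` is standardized:

```
Z = (fc − mean_q) / sd_q,   p = 1 − Φ(Z),   BH-adjust within quantile
```

Bins with FDR < 0.001 are enriched; candidate peaks survive iff they
overlap an enriched bin. Everything downstream (consensus, scoring,
contrasts, loops) is interval arithmetic and count statistics on
0-based half-open coordinates with ≥ 1 bp overlap semantics.

## Worked example

```python
import chromfusion as cf

genome = cf.make_genome(4, 3e6, seed=7)          # 12 Mb, 30000 bins
truth  = cf.make_truth(genome, seed=7)           # 10 planted fold-8 regions
ip, inp = cf.simulate_pair_tracks(genome, truth, seed=7)
res = cf.call_enriched_bins(ip, inp)
print(int(res["enriched"].sum()))                # 21 enriched bins

loops = cf.simulate_loops(truth, genome, seed=7)
kept = cf.filter_loops(loops, 5)                 # counts > 5
targets = cf.assign_target_genes(
    cf.classify_loops(kept, truth.region_bins()),
    truth.gene_models, ea_peaks=truth.region_bins())
print(sorted(targets["gene_id"].unique()))
# ['target_0', ..., 'target_7']  — exactly the 8 planted wirings
```

The 21 flagged bins are the 20 planted ones (10 regions × 2 bins) plus
one borderline neighbor; every planted loop above the count filter maps
back to its planted target gene and nothing else.

The numbered drivers under `analysis/` run the full narrative and write
tables under `results/`:

```
python analysis/01_simulate_fixture.py        # fixture + truth JSON
python analysis/02_enrichment_calibration.py  # null FDR + planted-bin power
python analysis/03_consensus_annotation.py    # consensus, fusion split, TSS/Distal
python analysis/04_scoring_dynamics.py        # scores, correlations, de-novo recovery
python analysis/05_loop_connectivity.py       # loops, targets, differential, stats
python analysis/06_full_pipeline_report.py    # everything, one config
```

Representative output (seed 7): the enrichment caller flags 0.000 % of
null bins at FDR 0.001 and recovers 94 % of planted fold-8 bins; the
de-novo classifier reaches 99.8 % sensitivity at a 0.30 % false-positive
rate; replicate peak scores correlate at r = 0.92; depleting
fusion-associated loop counts 2.5-fold sends 6 of 8 EA loops below the
2-fold differential threshold while size factors stay at ≈1.0.

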