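"""Quantile-stratified fold-change Z-score enrichment calling on genome bins.

The caller scores every fixed-width bin as ``log2(count + pseudo)`` for
the IP and the Input sample, stratifies bins into abundance quantiles on
the mean score ``(IP + Input)/2``, and standardizes the log2 fold change
``IP − Input`` within each quantile.  Upper-tail normal p-values are
Benjamini–Hochberg adjusted (within each quantile by default) and bins
with FDR below the threshold are flagged enriched.  Externally produced
candidate peaks are then gated on overlap with enriched bins.

Abundance stratification is what makes the fold-change null comparable
across the dynamic range: low-count bins have noisy log-ratios, and a
single genome-wide SD would either drown high-count signal or flood the
low-count tail with false calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .intervals import merge_within, overlaps_any
from .tracks import BinTrack


def cap_redundant_reads(reads: pd.DataFrame, max_dup: int = 3) -> pd.DataFrame:
    """Retain at most ``max_dup`` reads with identical (chrom, start, end, strand).

    Order is stable: the first ``max_dup`` occurrences win.  Duplicate
    capping guards against PCR amplification artifacts that would
    otherwise masquerade as enrichment.
    """
    if max_dup < 1:
        raise ValueError("max_dup must be >= 1")
    if reads.empty:
        return reads.copy()
    keys = ["chrom", "start", "end"]
    if "strand" in reads.columns:
        keys.append("strand")
    rank = reads.groupby(keys, sort=False).cumcount()
    return reads.loc[rank < max_dup].reset_index(drop=True)


def shift_atac_reads(reads: pd.DataFrame, genome=None) -> pd.DataFrame:
    """Correct transposase-insertion offsets: + reads +4 bp, − reads −5 bp.

    The Tn5 transposase inserts adapters 9 bp apart, so cut sites are
    recovered by offsetting plus-strand alignments by +4 and minus-strand
    alignments by −5.  Coordinates are clipped at chromosome bounds when a
    genome is supplied (and at zero always).  Unstranded reads are rejected.
    """
    if reads.empty:
        return reads.copy()
    if "strand" not in reads.columns or (~reads["strand"].isin(["+", "-"])).any():
        raise ValueError("shift_atac_reads: every read must have strand + or -")
    out = reads.copy()
    shift = np.where(out["strand"].to_numpy() == "+", 4, -5)
    widths = out["end"].to_numpy() - out["start"].to_numpy()
    start = out["start"].to_numpy() + shift
    if genome is not None:
        limits = out["chrom"].map(genome.sizes).to_numpy()
        start = np.minimum(start, limits - widths)
    start = np.maximum(start, 0)
    out["start"] = start
    out["end"] = start + widths
    return out


def call_enriched_bins(
    ip: BinTrack,
    input_track: BinTrack,
    n_quantiles: int = 10,
    pseudo: float = 1.0,
    fdr_threshold: float = 0.001,
    bh_scope: str = "quantile",
) -> pd.DataFrame:
    """Flag enriched bins by within-quantile standardized log2 fold change.

    Returns one row per bin with columns: chrom, start, end, ip_count,
    input_count, ip_score, input_score, mean_score, quantile, fold_change,
    z, p, fdr, enriched.

    Notes
    -----
    * quantile membership is by rank of the mean score; ties are broken
      by genomic order (stable sort) and quantile sizes differ by <= 1.
    * a quantile whose fold changes have zero spread gives Z = 0 for all
      its bins (identical bins carry no evidence).
    * the SD is the sample standard deviation (ddof=1).
    * ``bh_scope="global"`` applies one BH correction genome-wide instead
      of per quantile.
    """
    if not ip.same_shape(input_track):
        raise ValueError("IP and Input tracks differ in bin width or genome")
    if n_quantiles < 1:
        raise ValueError("n_quantiles must be >= 1")
    if bh_scope not in ("quantile", "global"):
        raise ValueError("bh_scope must be 'quantile' or 'global'")
    frame = ip.bin_frame().rename(columns={"count": "ip_count"})
    frame["input_count"] = input_track.bin_frame()["count"]
    ip_score = np.log2(frame["ip_count"].to_numpy() + pseudo)
    input_score = np.log2(frame["input_count"].to_numpy() + pseudo)
    frame["ip_score"] = ip_score
    frame["input_score"] = input_score
    frame["mean_score"] = (ip_score + input_score) / 2
    frame["fold_change"] = ip_score - input_score

    n = len(frame)
    order = np.argsort(frame["mean_score"].to_numpy(), kind="stable")
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)
    quantile = rank * n_quantiles // max(n, 1)
    frame["quantile"] = quantile

    fc = frame["fold_change"].to_numpy()
    z = np.zeros(n)
    for q in range(n_quantiles):
        mask = quantile == q
        if mask.sum() < 2:
            continue
        sd = fc[mask].std(ddof=1)
        if sd > 0:
            z[mask] = (fc[mask] - fc[mask].mean()) / sd
    p = norm.sf(z)
    fdr = np.ones(n)
    if n:
        if bh_scope == "quantile":
            for q in range(n_quantiles):
                mask = quantile == q
                if mask.any():
                    fdr[mask] = multipletests(p[mask], method="fdr_bh")[1]
        else:
            fdr = multipletests(p, method="fdr_bh")[1]
    frame["z"] = z
    frame["p"] = p
    frame["fdr"] = fdr
    frame["enriched"] = fdr < fdr_threshold
    return frame


def enriched_regions(enrichment: pd.DataFrame) -> pd.DataFrame:
    """Merge flagged bins into disjoint enriched regions."""
    flagged = enrichment.loc[enrichment["enriched"], ["chrom", "start", "end"]]
    if flagged.empty:
        return flagged.reset_index(drop=True)
    return merge_within(flagged, gap=0)


def gate_candidate_peaks(candidates: pd.DataFrame, enrichment: pd.DataFrame) -> pd.DataFrame:
    """Keep candidate peaks that overlap (>= 1 bp) at least one enriched bin.

    Candidate coordinates and any score columns pass through unchanged.
    """
    if candidates.empty:
        return candidates.copy()
    flagged = enrichment.loc[enrichment["enriched"], ["chrom", "start", "end"]]
    keep = overlaps_any(candidates, flagged)
    return candidates.loc[keep].reset_index(drop=True)


def write_enrichment_tsv(enrichment: pd.DataFrame, path) -> None:
    cols = [
        "chrom", "start", "end", "ip_count", "input_count",
        "quantile", "fold_change", "z", "p", "fdr", "enriched",
    ]
    enrichment[cols].to_csv(path, sep="\t", index=False)
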