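"""Consensus peak architecture and genomic annotation.

Replicate peak calls are merged with a ±150 bp gap rule, consensus
regions require support from every replicate experiment, and the
consensus of one antibody is partitioned against a second antibody into
fusion-bound (overlap) and single-factor (no overlap) sites.  Every peak
is then annotated as TSS (within ±1 kb of a transcription start site, or
carrying promoter-mark support in all replicates) or Distal, and distal
peaks as intragenic/intergenic against gene bodies.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .intervals import check_intervals, merge_within, overlaps_any, sort_intervals

__all__ = [
    "merge_within",
    "consensus_regions",
    "define_fusion_peaks",
    "tss_windows",
    "annotate_tss_distal",
    "annotate_genomic_context",
    "distribution_stats",
    "round_half_up",
]


def consensus_regions(
    merged: pd.DataFrame,
    replicate_sets: list[pd.DataFrame],
    require_all: bool = True,
    min_sets: int | None = None,
) -> pd.DataFrame:
    """Keep merged regions supported by the replicate experiments.

    A region survives iff it overlaps >= 1 peak in every replicate set
    (``require_all``), or in at least ``min_sets`` sets when given.
    """
    if not replicate_sets:
        raise ValueError("at least one replicate set is required")
    check_intervals(merged, "merged")
    if merged.empty:
        return merged.copy()
    support = np.zeros(len(merged), dtype=int)
    for rep in replicate_sets:
        support += overlaps_any(merged, rep).astype(int)
    needed = len(replicate_sets) if require_all else (min_sets if min_sets is not None else 1)
    return merged.loc[support >= needed].reset_index(drop=True)


def define_fusion_peaks(
    setA_consensus: pd.DataFrame, setB_consensus: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition consensus set A by overlap with consensus set B.

    Returns ``(fusion, a_only)``: A-regions overlapping (>= 1 bp) any
    B-region, and A-regions with zero B overlap.  The two buckets are
    disjoint and together cover A.
    """
    check_intervals(setA_consensus, "setA")
    check_intervals(setB_consensus, "setB")
    hit = overlaps_any(setA_consensus, setB_consensus)
    fusion = setA_consensus.loc[hit].reset_index(drop=True)
    a_only = setA_consensus.loc[~hit].reset_index(drop=True)
    return fusion, a_only


def tss_windows(genes: pd.DataFrame, flank: int = 1000) -> pd.DataFrame:
    """Promoter windows ``[tss - flank, tss + flank + 1)`` per gene.

    The window is closed on both ends in display coordinates; half-open
    internally, hence the ``+ 1``.
    """
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": np.maximum(genes["tss"].to_numpy() - flank, 0),
            "end": genes["tss"].to_numpy() + flank + 1,
            "gene_id": genes["gene_id"],
        }
    )
    return out.reset_index(drop=True)


def annotate_tss_distal(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    tss_window: int = 1000,
    h3k4me3_sets: list[pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Label each peak TSS or Distal.

    A peak is TSS if it overlaps any gene's ``tss ± tss_window`` window,
    or failing that, if it overlaps promoter-mark (H3K4me3) enriched
    regions in ALL supplied replicate sets.  Everything else is Distal.
    Genes on chromosomes absent from the peak set are fine; peak
    chromosomes absent from the gene table simply never match.
    """
    check_intervals(peaks, "peaks")
    out = peaks.copy().reset_index(drop=True)
    windows = tss_windows(genes, tss_window)
    is_tss = overlaps_any(out, windows)
    if h3k4me3_sets:
        mark_support = np.ones(len(out), dtype=bool)
        for mark in h3k4me3_sets:
            mark_support &= overlaps_any(out, mark)
        is_tss |= mark_support
    out["locus_class"] = np.where(is_tss, "TSS", "Distal")
    return out


def annotate_genomic_context(distal_peaks: pd.DataFrame, gene_bodies: pd.DataFrame) -> pd.DataFrame:
    """Label distal peaks intragenic (>= 1 bp gene-body overlap) or intergenic."""
    out = distal_peaks.copy().reset_index(drop=True)
    inside = overlaps_any(out, gene_bodies)
    out["context"] = np.where(inside, "intragenic", "intergenic")
    return out


def round_half_up(x: float) -> int:
    """Round half away from zero, matching printed integer percentages."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def distribution_stats(annotated: pd.DataFrame) -> pd.DataFrame:
    """Fractions of TSS/Distal peaks (and intragenic/intergenic among Distal).

    Returns a table with count, fraction, and integer percent
    (round-half-away-from-zero) per class.  Fractions sum to 1 within
    each level.  Empty input is an error.
    """
    if annotated.empty:
        raise ValueError("distribution_stats: empty peak set")
    total = len(annotated)
    rows = []
    for cls in ("TSS", "Distal"):
        n = int((annotated["locus_class"] == cls).sum())
        rows.append(("locus", cls, n, n / total, round_half_up(100 * n / total)))
    if "context" in annotated.columns:
        distal = annotated.loc[annotated["locus_class"] == "Distal"]
        n_distal = len(distal)
        if n_distal:
            for ctx in ("intragenic", "intergenic"):
                n = int((distal["context"] == ctx).sum())
                rows.append(("context", ctx, n, n / n_distal, round_half_up(100 * n / n_distal)))
    return pd.DataFrame(rows, columns=["level", "class", "count", "fraction", "percent"])
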