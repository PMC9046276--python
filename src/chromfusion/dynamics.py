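"""Condition-contrast chromatin behavior.

Three classifiers over paired control/treated samples:

* three-way site categories by partner-factor occupancy — a reference
  site lacks the partner in both conditions (NoATF1), gains it only in
  the treated condition (DeNovo), or carries it in both and shows a
  score increase (PreExisting; without increase the site is Dropped);
* de-novo activated regions after a perturbation — fewer than 5 raw
  reads in control and a greater-than-4-fold normalized gain;
* two-condition differential peaks at a |log2 score difference| > 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import check_intervals, merge_within, overlaps_any

CATEGORIES = ("NoATF1", "DeNovo", "PreExisting", "Dropped")


def build_condition_union(
    peak_sets_with_tags: dict[str, pd.DataFrame], gap: int = 150
) -> pd.DataFrame:
    """Pool tagged peak sets into disjoint regions with per-tag presence.

    All peaks are combined, regions within ``gap`` bp are pooled, and
    each pooled region records which condition contributed >= 1 peak.
    """
    if not peak_sets_with_tags:
        raise ValueError("no peak sets supplied")
    frames = []
    for tag, df in peak_sets_with_tags.items():
        check_intervals(df, f"peaks[{tag}]")
        frames.append(df[["chrom", "start", "end"]])
    union = merge_within(pd.concat(frames, ignore_index=True), gap=gap)
    for tag, df in peak_sets_with_tags.items():
        union[f"present_{tag}"] = overlaps_any(union, df)
    return union


def classify_sites(
    reference_sites: pd.DataFrame,
    partner_peaks_ctl: pd.DataFrame,
    partner_peaks_treated: pd.DataFrame,
    score_ctl: np.ndarray,
    score_treated: np.ndarray,
) -> pd.DataFrame:
    """Categorize reference sites by partner-factor occupancy and score change.

    Overlap is >= 1 bp.  Categories partition the input:
    NoATF1 (absent/absent), DeNovo (absent in control, present treated),
    PreExisting (present/present with score_treated > score_ctl),
    Dropped (present/present without increase).
    """
    check_intervals(reference_sites, "reference_sites")
    score_ctl = np.asarray(score_ctl, dtype=float)
    score_treated = np.asarray(score_treated, dtype=float)
    if len(score_ctl) != len(reference_sites) or len(score_treated) != len(reference_sites):
        raise ValueError("scores are not aligned to reference sites")
    out = reference_sites.copy().reset_index(drop=True)
    in_ctl = overlaps_any(out, partner_peaks_ctl)
    in_treated = overlaps_any(out, partner_peaks_treated)
    increase = score_treated > score_ctl
    category = np.full(len(out), "NoATF1", dtype=object)
    category[~in_ctl & in_treated] = "DeNovo"
    category[in_ctl & in_treated & increase] = "PreExisting"
    category[in_ctl & in_treated & ~increase] = "Dropped"
    # present only in control: partner was lost; grouped with Dropped for
    # bookkeeping (not part of the three named gain categories)
    category[in_ctl & ~in_treated] = "Dropped"
    out["atf1_in_ctl"] = in_ctl
    out["atf1_in_treated"] = in_treated
    out["score_increase"] = increase
    out["score_ctl"] = score_ctl
    out["score_treated"] = score_treated
    out["category"] = category
    return out


def restrict_to_reference(
    sites: pd.DataFrame,
    reference: pd.DataFrame,
    exclude: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Optional pre-filter: keep sites overlapping a reference peak set and
    absent from an exclusion (control) set."""
    keep = overlaps_any(sites, reference)
    if exclude is not None and len(exclude):
        keep &= ~overlaps_any(sites, exclude)
    return sites.loc[keep].reset_index(drop=True)


def call_de_novo_peaks(
    union: pd.DataFrame,
    counts_ctl: np.ndarray,
    counts_treated: np.ndarray,
    libsize_ctl: float | None = None,
    libsize_treated: float | None = None,
    max_ctl_reads: float = 5.0,
    min_fc: float = 4.0,
    fc_on_raw: bool = False,
) -> pd.DataFrame:
    """Regions activated from (near-)zero: < ``max_ctl_reads`` raw control
    reads AND a normalized pseudo-counted fold change > ``min_fc``.

    Fold change = (treated_norm + 1) / (ctl_norm + 1) where norm scales
    counts to the mean of the two library sizes (raw counts when sizes
    are omitted or ``fc_on_raw``).  Both inequalities are strict.
    """
    counts_ctl = np.asarray(counts_ctl, dtype=float)
    counts_treated = np.asarray(counts_treated, dtype=float)
    if len(counts_ctl) != len(union) or len(counts_treated) != len(union):
        raise ValueError("counts are not aligned to union regions")
    if libsize_ctl is None or libsize_treated is None or fc_on_raw:
        norm_ctl, norm_treated = counts_ctl, counts_treated
    else:
        target = (libsize_ctl + libsize_treated) / 2
        norm_ctl = counts_ctl * target / libsize_ctl
        norm_treated = counts_treated * target / libsize_treated
    fc = (norm_treated + 1) / (norm_ctl + 1)
    out = union.copy().reset_index(drop=True)
    out["ctl_reads"] = counts_ctl
    out["treated_reads"] = counts_treated
    out["fold_change"] = fc
    out["de_novo"] = (counts_ctl < max_ctl_reads) & (fc > min_fc)
    return out


def differential_peaks(
    union: pd.DataFrame,
    score_ctl: np.ndarray,
    score_treated: np.ndarray,
    log2fc_threshold: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split union regions on the score difference (treated − control).

    increased: delta > threshold; decreased: delta < −threshold; strict
    at both boundaries, buckets disjoint.
    """
    score_ctl = np.asarray(score_ctl, dtype=float)
    score_treated = np.asarray(score_treated, dtype=float)
    delta = score_treated - score_ctl
    out = union.copy().reset_index(drop=True)
    out["delta_score"] = delta
    increased = out.loc[delta > log2fc_threshold].reset_index(drop=True)
    decreased = out.loc[delta < -log2fc_threshold].reset_index(drop=True)
    return increased, decreased
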