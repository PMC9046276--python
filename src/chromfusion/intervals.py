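"""Interval arithmetic on 0-based half-open genomic coordinates.

All peak, bin, and anchor operations in the package reduce to three
primitives defined here: gap-tolerant merging, "overlaps any" membership
against a disjoint subject set, and a general many-to-many overlap join.
Overlap always means >= 1 bp of intersection under half-open arithmetic:
[a, b) and [c, d) overlap iff a < d and c < b.

Intervals travel as pandas DataFrames with at least the columns
``chrom`` (str), ``start`` (int), ``end`` (int).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

INTERVAL_COLUMNS = ["chrom", "start", "end"]


def check_intervals(df: pd.DataFrame, name: str = "intervals") -> pd.DataFrame:
    """Validate an interval frame: required columns and 0 <= start < end."""
    for col in INTERVAL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{name}: missing column {col!r}")
    if len(df) and ((df["start"] < 0).any() or (df["start"] >= df["end"]).any()):
        bad = df[(df["start"] < 0) | (df["start"] >= df["end"])]
        raise ValueError(f"{name}: {len(bad)} interval(s) violate 0 <= start < end")
    return df


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def merge_within(df: pd.DataFrame, gap: int = 150) -> pd.DataFrame:
    """Union intervals that overlap or whose gap is <= ``gap`` bp, transitively.

    Two intervals on the same chromosome are pooled when
    ``next.start - current.end <= gap``; the result is disjoint with all
    pairwise gaps > gap.  ``gap=0`` merges touching/overlapping intervals
    only.  Idempotent.
    """
    if gap < 0:
        raise ValueError(f"gap must be >= 0, got {gap}")
    check_intervals(df)
    if df.empty:
        return df.loc[:, INTERVAL_COLUMNS].copy()
    df = sort_intervals(df[INTERVAL_COLUMNS])
    out_chrom: list[str] = []
    out_start: list[int] = []
    out_end: list[int] = []
    for chrom, grp in df.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= gap:
                cur_e = max(cur_e, int(e))
            else:
                out_chrom.append(chrom)
                out_start.append(cur_s)
                out_end.append(cur_e)
                cur_s, cur_e = int(s), int(e)
        out_chrom.append(chrom)
        out_start.append(cur_s)
        out_end.append(cur_e)
    return pd.DataFrame({"chrom": out_chrom, "start": out_start, "end": out_end})


def _disjoint_index(subject: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge the subject set (gap=0 semantics: overlap only) and index per chrom."""
    merged = merge_within(subject, gap=0) if len(subject) else subject
    index = {}
    for chrom, grp in merged.groupby("chrom"):
        index[chrom] = (grp["start"].to_numpy(), grp["end"].to_numpy())
    return index


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: does it overlap (>= 1 bp) any subject interval?"""
    check_intervals(query, "query")
    check_intervals(subject, "subject")
    out = np.zeros(len(query), dtype=bool)
    if query.empty or subject.empty:
        return out
    index = _disjoint_index(subject)
    chroms = query["chrom"].to_numpy()
    qs = query["start"].to_numpy()
    qe = query["end"].to_numpy()
    for chrom in np.unique(chroms):
        if chrom not in index:
            continue
        s_starts, s_ends = index[chrom]
        mask = chroms == chrom
        # subjects are disjoint & sorted: the only candidate for query
        # [a, b) is the last subject with start < b.
        pos = np.searchsorted(s_starts, qe[mask], side="left") - 1
        valid = pos >= 0
        hit = np.zeros(mask.sum(), dtype=bool)
        hit[valid] = s_ends[pos[valid]] > qs[mask][valid]
        out[mask] = hit
    return out


def overlap_join(left: pd.DataFrame, right: pd.DataFrame) -> pd.DataFrame:
    """All overlapping (left, right) index pairs; many-to-many.

    Returns a DataFrame with columns ``left_index`` and ``right_index``
    referring to positional indices of the inputs.
    """
    check_intervals(left, "left")
    check_intervals(right, "right")
    if left.empty or right.empty:
        return pd.DataFrame({"left_index": [], "right_index": []}, dtype=int)
    li: list[int] = []
    ri: list[int] = []
    trees: dict[str, IntervalTree] = {}
    for p, (chrom, s, e) in enumerate(zip(right["chrom"], right["start"], right["end"])):
        trees.setdefault(chrom, IntervalTree()).addi(int(s), int(e), p)
    for p, (chrom, s, e) in enumerate(zip(left["chrom"], left["start"], left["end"])):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree.overlap(int(s), int(e)):
            li.append(p)
            ri.append(iv.data)
    out = pd.DataFrame({"left_index": li, "right_index": ri}, dtype=int)
    return out.sort_values(["left_index", "right_index"]).reset_index(drop=True)
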