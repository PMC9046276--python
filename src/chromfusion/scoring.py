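"""Normalized per-peak ChIP scores, flooring, correlation, quantile normalization.

The peak score is ``log2(IP + 1) − log2(Input + 1)`` on read counts
normalized to a 20 M-read library and a 500-bp peak width, so scores are
comparable across samples of different depth and peaks of different
size.  Peaks whose raw IP count falls below the mean Input peak count of
the dataset are floored to score 0 (no credible signal above chromatin
background), and replicate scores are averaged after flooring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def score_peaks(
    peaks: pd.DataFrame,
    ip_counts: np.ndarray,
    input_counts: np.ndarray,
    ip_libsize: float,
    input_libsize: float,
    target_reads: float = 2e7,
    target_width: float = 500.0,
) -> pd.DataFrame:
    """Build a score table for one sample over ``peaks``.

    norm = raw × (target_reads / libsize) × (target_width / peak_width);
    score = log2(norm_IP + 1) − log2(norm_Input + 1).

    Peaks narrower than ``target_width`` are up-scaled by the same
    formula; zero-width peaks are rejected.
    """
    if ip_libsize <= 0 or input_libsize <= 0:
        raise ValueError("library sizes must be positive")
    ip_counts = np.asarray(ip_counts, dtype=float)
    input_counts = np.asarray(input_counts, dtype=float)
    if len(ip_counts) != len(peaks) or len(input_counts) != len(peaks):
        raise ValueError("counts are not aligned to peaks")
    widths = peaks["end"].to_numpy() - peaks["start"].to_numpy()
    if (widths <= 0).any():
        raise ValueError("zero-width peak in score_peaks")
    norm_ip = ip_counts * (target_reads / ip_libsize) * (target_width / widths)
    norm_input = input_counts * (target_reads / input_libsize) * (target_width / widths)
    out = peaks[["chrom", "start", "end"]].copy().reset_index(drop=True)
    out["raw_ip"] = ip_counts
    out["raw_input"] = input_counts
    out["norm_ip"] = norm_ip
    out["norm_input"] = norm_input
    out["score"] = np.log2(norm_ip + 1) - np.log2(norm_input + 1)
    return out


def apply_input_floor(table: pd.DataFrame, use_normalized: bool = False) -> pd.DataFrame:
    """Floor scores of weak peaks to zero.

    The threshold is the mean Input peak read count of the dataset; any
    peak whose IP read count falls below it gets score 0.  Raw counts are
    used by default (``use_normalized=True`` switches both sides to the
    normalized counts).  Idempotent: counts are untouched, so a second
    application floors the same rows.
    """
    ip_col, input_col = ("norm_ip", "norm_input") if use_normalized else ("raw_ip", "raw_input")
    out = table.copy()
    threshold = float(out[input_col].mean()) if len(out) else 0.0
    floored = out[ip_col].to_numpy() < threshold
    out.loc[floored, "score"] = 0.0
    out["floored"] = floored
    return out


def average_replicates(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Cellwise mean of replicate scores (applied after flooring)."""
    if not tables:
        raise ValueError("no replicate tables")
    base = tables[0][["chrom", "start", "end"]].reset_index(drop=True)
    for t in tables[1:]:
        other = t[["chrom", "start", "end"]].reset_index(drop=True)
        if not base.equals(other):
            raise ValueError("replicate tables have mismatched peak indices")
    out = base.copy()
    out["score"] = np.mean([t["score"].to_numpy() for t in tables], axis=0)
    return out


def pearson_matrix(table: pd.DataFrame, columns: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r with two-sided p-values over the given columns.

    Returns (matrix, long) where ``matrix`` is the symmetric r matrix
    (diagonal 1) and ``long`` holds one row per pair: (col_a, col_b, r,
    p, n, note).  A zero-variance column yields NaN with an explanatory
    note rather than an error.
    """
    if len(table) < 3:
        raise ValueError("pearson_matrix requires >= 3 peaks")
    k = len(columns)
    mat = pd.DataFrame(np.eye(k), index=columns, columns=columns)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            x = table[columns[i]].to_numpy(dtype=float)
            y = table[columns[j]].to_numpy(dtype=float)
            if not (np.isfinite(x).all() and np.isfinite(y).all()):
                raise ValueError("non-finite values in correlation input")
            if np.std(x) == 0 or np.std(y) == 0:
                r, p, note = np.nan, np.nan, "zero-variance column"
            else:
                r, p = stats.pearsonr(x, y)
                note = ""
            mat.iloc[i, j] = mat.iloc[j, i] = r
            rows.append((columns[i], columns[j], r, p, len(x), note))
    long = pd.DataFrame(rows, columns=["col_a", "col_b", "r", "p", "n", "note"])
    return mat, long


def quantile_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Classical rank-based quantile normalization across columns.

    Each column is replaced by the mean of the column-wise sorted values
    at its ranks; ties within a column receive the average of the values
    their ranks span.  After normalization all columns have identical
    sorted values.
    """
    if table.shape[1] < 2:
        raise ValueError("quantile normalization requires >= 2 samples")
    arr = table.to_numpy(dtype=float)
    n, k = arr.shape
    sorted_cols = np.sort(arr, axis=0)
    row_means = sorted_cols.mean(axis=1)
    out = np.empty_like(arr)
    for j in range(k):
        order = np.argsort(arr[:, j], kind="stable")
        assigned = np.empty(n)
        assigned[order] = row_means
        # ties: every member of a run of equal input values receives the
        # mean of the row means their ranks span
        tied = pd.Series(assigned).groupby(arr[:, j]).transform("mean").to_numpy()
        out[:, j] = tied
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def quantile_normalize_scores(
    table: pd.DataFrame, score_threshold: float = 3.5
) -> tuple[pd.DataFrame, dict[str, pd.Index]]:
    """Quantile-normalize a peak × sample score table and gate on a cutoff.

    Returns the normalized table and, per sample, the index of peaks
    whose normalized score is strictly above ``score_threshold``.
    """
    normalized = quantile_normalize(table)
    retained = {
        col: normalized.index[normalized[col] > score_threshold] for col in normalized.columns
    }
    return normalized, retained


def top_tss_control_set(table: pd.DataFrame, score_columns: list[str], n: int = 374) -> pd.DataFrame:
    """The ``n`` promoter windows with the highest mean-of-conditions score.

    ``table`` must carry a ``gene_id`` column; ties at the boundary are
    broken by lexicographic gene id.
    """
    if n > len(table):
        raise ValueError(f"requested top {n} of only {len(table)} windows")
    work = table.copy()
    work["_mean_score"] = work[score_columns].mean(axis=1)
    work = work.sort_values(["_mean_score", "gene_id"], ascending=[False, True], kind="stable")
    return work.head(n).drop(columns="_mean_score").reset_index(drop=True)
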