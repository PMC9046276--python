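"""Chromatin loop filtering, classification, target-gene assignment, and
differential analysis.

Loops are anchor pairs with interaction counts (from an H3K27ac HiChIP
style assay).  The pipeline keeps loops with counts strictly above 5,
classifies a loop as fusion-associated (EA) when either anchor overlaps
a fusion-protein binding site, links loops to genes whose promoter
(TSS ± 1 kb) overlaps an anchor, normalizes paired-condition counts with
median-of-ratios size factors, and calls 2-fold differential loops.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import check_intervals, overlap_join, overlaps_any
from .peaks import tss_windows

LOOP_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "count"]


def _anchor_frame(loops: pd.DataFrame, which: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": loops[f"chrom{which}"].to_numpy(),
            "start": loops[f"start{which}"].to_numpy(),
            "end": loops[f"end{which}"].to_numpy(),
        }
    )


def check_loops(loops: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a loop table.

    Inter-chromosomal pairs are rejected (dropped with a count report):
    the analysis concerns cis connectivity.  Anchor1 is put first in
    genome order, and the midpoint-to-midpoint ``length`` is derived.
    """
    for col in LOOP_COLUMNS:
        if col not in loops.columns:
            raise ValueError(f"loop table missing column {col!r}")
    out = loops.copy().reset_index(drop=True)
    trans = (out["chrom1"] != out["chrom2"]).to_numpy()
    if trans.any():
        warnings.warn(f"check_loops: rejected {int(trans.sum())} inter-chromosomal loop(s)")
        out = out.loc[~trans].reset_index(drop=True)
    if (out["count"] < 0).any():
        raise ValueError("negative loop counts")
    swap = (out["start1"] > out["start2"]).to_numpy()
    if swap.any():
        a = out.loc[swap, ["chrom1", "start1", "end1"]].to_numpy()
        out.loc[swap, ["chrom1", "start1", "end1"]] = out.loc[
            swap, ["chrom2", "start2", "end2"]
        ].to_numpy()
        out.loc[swap, ["chrom2", "start2", "end2"]] = a
    mid1 = (out["start1"] + out["end1"]) // 2
    mid2 = (out["start2"] + out["end2"]) // 2
    out["length"] = (mid2 - mid1).abs()
    return out


def filter_loops(loops: pd.DataFrame, min_count: float = 5) -> pd.DataFrame:
    """Keep loops with count strictly greater than ``min_count``."""
    return loops.loc[loops["count"] > min_count].reset_index(drop=True)


def classify_loops(loops: pd.DataFrame, ea_peaks: pd.DataFrame) -> pd.DataFrame:
    """Set ``ea_associated``: either anchor overlaps (>= 1 bp) a fusion peak."""
    out = loops.copy().reset_index(drop=True)
    hit1 = overlaps_any(_anchor_frame(out, 1), ea_peaks)
    hit2 = overlaps_any(_anchor_frame(out, 2), ea_peaks)
    out["ea_associated"] = hit1 | hit2
    return out


def assign_target_genes(
    loops: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_flank: int = 1000,
    ea_peaks: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Map loops to genes whose promoter (TSS ± flank) overlaps an anchor.

    Returns a long many-to-many table (gene_id, loop_id, via_anchor,
    ea_associated).  When ``ea_peaks`` is given, ``ea_associated`` marks
    genes that are targets *of the peak set*: one anchor of the loop
    overlaps a peak and the gene promoter overlaps an anchor of the same
    loop.
    """
    promoters = tss_windows(genes, promoter_flank)
    rows = []
    peak_hits = {}
    if ea_peaks is not None:
        peak_hits[1] = overlaps_any(_anchor_frame(loops, 1), ea_peaks)
        peak_hits[2] = overlaps_any(_anchor_frame(loops, 2), ea_peaks)
    for which in (1, 2):
        anchors = _anchor_frame(loops, which)
        pairs = overlap_join(anchors, promoters[["chrom", "start", "end"]])
        for li, pi in zip(pairs["left_index"], pairs["right_index"]):
            ea = bool(peak_hits[1][li] or peak_hits[2][li]) if ea_peaks is not None else False
            rows.append((promoters["gene_id"].iloc[pi], int(li), which, ea))
    out = pd.DataFrame(rows, columns=["gene_id", "loop_id", "via_anchor", "ea_associated"])
    return out.drop_duplicates(["gene_id", "loop_id", "via_anchor"]).reset_index(drop=True)


def normalize_loop_counts(
    counts_a: np.ndarray, counts_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """Median-of-ratios size-factor normalization for two matched conditions.

    The reference per loop is the geometric mean of the two counts; the
    size factor of a condition is the median ratio to the reference over
    loops nonzero in both.  Normalized count = raw / size factor.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("conditions must be matched loop-by-loop")
    both = (a > 0) & (b > 0)
    if not both.any():
        raise ValueError("no loop has nonzero counts in both conditions")
    ref = np.sqrt(a[both] * b[both])
    sf_a = float(np.median(a[both] / ref))
    sf_b = float(np.median(b[both] / ref))
    return a / sf_a, b / sf_b, {"a": sf_a, "b": sf_b}


def differential_loops(
    norm_a: np.ndarray, norm_b: np.ndarray, fold: float = 2.0
) -> pd.DataFrame:
    """Direction per loop from pseudo-counted normalized ratios.

    increased: (norm_b + 1) / (norm_a + 1) >= fold; decreased symmetric;
    stable otherwise.
    """
    a = np.asarray(norm_a, dtype=float)
    b = np.asarray(norm_b, dtype=float)
    ratio_up = (b + 1) / (a + 1)
    ratio_down = (a + 1) / (b + 1)
    direction = np.full(len(a), "stable", dtype=object)
    direction[ratio_up >= fold] = "increased"
    direction[ratio_down >= fold] = "decreased"
    return pd.DataFrame(
        {"norm_a": a, "norm_b": b, "fold_change": ratio_up, "direction": direction}
    )


def loop_stats(loops: pd.DataFrame, anchors: pd.DataFrame) -> dict:
    """Per-anchor loop burden summarized by anchor class, with a Welch test.

    ``anchors`` is an interval frame with a ``class`` column (e.g. EA /
    non-EA).  For each anchor: the number of loops touching it and their
    total counts.  Per class: median, quartiles, whiskers at 1.5×IQR.
    Classes with < 2 anchors get summaries but no test.
    """
    check_intervals(anchors, "anchors")
    if "class" not in anchors.columns:
        raise ValueError("anchors need a 'class' column")
    n_loops = np.zeros(len(anchors))
    total_counts = np.zeros(len(anchors))
    for which in (1, 2):
        pairs = overlap_join(anchors[["chrom", "start", "end"]], _anchor_frame(loops, which))
        for ai, li in zip(pairs["left_index"], pairs["right_index"]):
            n_loops[ai] += 1
            total_counts[ai] += float(loops["count"].iloc[li])
    per_anchor = anchors.copy().reset_index(drop=True)
    per_anchor["n_loops"] = n_loops
    per_anchor["total_counts"] = total_counts

    def summary(values: np.ndarray) -> dict:
        q1, med, q3 = np.percentile(values, [25, 50, 75]) if len(values) else (np.nan,) * 3
        iqr = q3 - q1
        in_whisker = values[(values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)] if len(values) else values
        return {
            "n": int(len(values)),
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "whisker_low": float(in_whisker.min()) if len(in_whisker) else np.nan,
            "whisker_high": float(in_whisker.max()) if len(in_whisker) else np.nan,
        }

    classes = sorted(per_anchor["class"].unique())
    out: dict = {"per_anchor": per_anchor, "classes": {}}
    for cls in classes:
        sub = per_anchor.loc[per_anchor["class"] == cls]
        out["classes"][cls] = {
            "loops_per_anchor": summary(sub["n_loops"].to_numpy()),
            "counts_per_anchor": summary(sub["total_counts"].to_numpy()),
        }
    if len(classes) == 2:
        a = per_anchor.loc[per_anchor["class"] == classes[0]]
        b = per_anchor.loc[per_anchor["class"] == classes[1]]
        if len(a) >= 2 and len(b) >= 2:
            tests = {}
            for col in ("n_loops", "total_counts"):
                x, y = a[col].to_numpy(), b[col].to_numpy()
                if np.allclose(x, x.mean()) and np.allclose(y, y.mean()) and np.isclose(x.mean(), y.mean()):
                    t, p = 0.0, 1.0  # identical degenerate classes: no difference
                else:
                    t, p = stats.ttest_ind(x, y, equal_var=False)
                tests[col] = {"t": float(t), "p": float(p)}
            out["welch_t"] = tests
        else:
            out["welch_t"] = None
            out["test_skipped_reason"] = "a class has fewer than 2 anchors"
    return out


def intersect_targets_with_deg(
    target_genes: list[str] | pd.Series,
    deg_table: pd.DataFrame,
    fc: float = 1.5,
    padj: float = 0.05,
) -> dict:
    """Split target genes by differential expression.

    A gene qualifies when adj_p < ``padj`` and |linear fold change| >
    ``fc`` (i.e. |log2fc| > log2(fc)); qualifying genes split by sign.
    Genes absent from the table are counted as untested.
    """
    for col in ("gene", "log2fc", "adj_p"):
        if col not in deg_table.columns:
            raise ValueError(f"deg_table missing column {col!r}")
    targets = pd.Index(pd.unique(pd.Series(list(target_genes))))
    table = deg_table.set_index("gene")
    tested = targets[targets.isin(table.index)]
    untested = targets.difference(tested)
    sub = table.loc[tested]
    log2_cut = np.log2(fc)
    sig = (sub["adj_p"] < padj) & (sub["log2fc"].abs() > log2_cut)
    down = sorted(sub.index[sig & (sub["log2fc"] < 0)])
    up = sorted(sub.index[sig & (sub["log2fc"] > 0)])
    return {
        "down": down,
        "up": up,
        "n_tested": int(len(tested)),
        "n_untested": int(len(untested)),
    }


def write_loops(loops: pd.DataFrame, path) -> None:
    loops[LOOP_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_loops(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=LOOP_COLUMNS)
    return check_loops(df)
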