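"""Read-derived signal containers: fixed-width bin counts and per-base coverage.

The bin track is the substrate of the enrichment caller: the genome is
split into fixed-width bins (400 bp by default) and each retained read is
assigned to the bin containing its 5' position.  Per-base coverage tracks
(reads extended to fragment length, optionally CPM-scaled) serve the
signal-profile operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import Genome

DEFAULT_BIN_WIDTH = 400


@dataclass
class BinTrack:
    """Per-chromosome ordered bin count vectors for one sample.

    ``counts[chrom][i]`` covers ``[i*bin_width, (i+1)*bin_width)``;
    ``library_size`` is the total number of retained (assigned) reads.
    """

    bin_width: int
    counts: dict[str, np.ndarray]
    library_size: int

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for chrom, vec in self.counts.items():
            if (np.asarray(vec) < 0).any():
                raise ValueError(f"negative bin counts on {chrom}")

    @property
    def n_bins(self) -> int:
        return int(sum(len(v) for v in self.counts.values()))

    def flat(self) -> np.ndarray:
        """All bin counts concatenated in chromosome order."""
        return np.concatenate([self.counts[c] for c in self.counts]) if self.counts else np.array([])

    def bin_frame(self) -> pd.DataFrame:
        """Bins as an interval frame with a ``count`` column."""
        rows = []
        for chrom, vec in self.counts.items():
            starts = np.arange(len(vec)) * self.bin_width
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": starts + self.bin_width,
                        "count": vec,
                    }
                )
            )
        if not rows:
            return pd.DataFrame(columns=["chrom", "start", "end", "count"])
        return pd.concat(rows, ignore_index=True)

    def same_shape(self, other: "BinTrack") -> bool:
        return self.bin_width == other.bin_width and {
            c: len(v) for c, v in self.counts.items()
        } == {c: len(v) for c, v in other.counts.items()}


def bin_counts(reads: pd.DataFrame, genome: Genome, bin_width: int = DEFAULT_BIN_WIDTH) -> BinTrack:
    """Assign each read to the bin containing its 5' position.

    The 5' position is ``start`` for + / unstranded reads and ``end - 1``
    for − strand reads.  Reads on chromosomes absent from ``genome`` are
    rejected (dropped) with a count report; the remaining total defines
    ``library_size``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    nbins = genome.n_bins(bin_width)
    counts = {c: np.zeros(n, dtype=np.int64) for c, n in nbins.items()}
    if len(reads) == 0:
        return BinTrack(bin_width, counts, 0)
    known = reads["chrom"].isin(genome.sizes).to_numpy()
    n_rejected = int((~known).sum())
    if n_rejected:
        warnings.warn(f"bin_counts: rejected {n_rejected} read(s) on unknown chromosomes")
    kept = reads.loc[known]
    if "strand" in kept.columns:
        minus = (kept["strand"] == "-").to_numpy()
    else:
        minus = np.zeros(len(kept), dtype=bool)
    pos = np.where(minus, kept["end"].to_numpy() - 1, kept["start"].to_numpy())
    bins = pos // bin_width
    for chrom, grp_bins in pd.Series(bins).groupby(kept["chrom"].to_numpy()):
        vec = counts[chrom]
        clipped = np.clip(grp_bins.to_numpy(), 0, len(vec) - 1)
        np.add.at(vec, clipped, 1)
    return BinTrack(bin_width, counts, int(len(kept)))


def make_coverage_track(
    reads: pd.DataFrame,
    genome: Genome,
    fragment_extension: int = 300,
    normalize: str = "none",
) -> dict[str, np.ndarray]:
    """Per-base coverage with reads extended to ``fragment_extension`` bp.

    Each read is extended from its 5' end in its strand direction to the
    fragment length; reads already longer than the extension are kept
    as-is (no-op with a warning).  ``normalize="CPM"`` divides by
    library_size / 1e6.
    """
    if normalize not in ("none", "CPM"):
        raise ValueError(f"normalize must be 'none' or 'CPM', got {normalize!r}")
    cov = {c: np.zeros(l, dtype=float) for c, l in genome.sizes.items()}
    if len(reads) == 0:
        return cov
    lengths = reads["end"].to_numpy() - reads["start"].to_numpy()
    if (lengths > fragment_extension).any():
        warnings.warn(
            "make_coverage_track: some reads exceed fragment_extension; kept at original length"
        )
    reads = reads.copy()
    if "strand" not in reads.columns:
        reads["strand"] = "+"
    for chrom, grp in reads.groupby("chrom"):
        if chrom not in cov:
            continue
        vec = cov[chrom]
        L = len(vec)
        s = grp["start"].to_numpy().copy()
        e = grp["end"].to_numpy().copy()
        st = grp["strand"].to_numpy()
        ext = np.maximum(e - s, fragment_extension)
        new_s = np.where(st == "-", e - ext, s)
        new_e = np.where(st == "-", e, s + ext)
        new_s = np.clip(new_s, 0, L)
        new_e = np.clip(new_e, 0, L)
        delta = np.zeros(L + 1)
        np.add.at(delta, new_s, 1.0)
        np.add.at(delta, new_e, -1.0)
        vec += np.cumsum(delta[:-1])
    if normalize == "CPM":
        scale = 1e6 / max(len(reads), 1)
        for chrom in cov:
            cov[chrom] *= scale
    return cov


def mean_signal_profile(
    track: dict[str, np.ndarray],
    sites: pd.DataFrame,
    flank: int = 500,
) -> tuple[pd.Series, float]:
    """Mean per-base signal in ``[center - flank, center + flank)`` per site.

    ``center`` is the site midpoint.  Windows are clipped at chromosome
    edges and the mean uses the effective (clipped) width.  Returns the
    per-site means and their aggregate mean (nan for an empty site list).
    """
    means = np.full(len(sites), np.nan)
    for i, (chrom, s, e) in enumerate(zip(sites["chrom"], sites["start"], sites["end"])):
        if chrom not in track:
            continue
        vec = track[chrom]
        center = (int(s) + int(e)) // 2
        lo = max(0, center - flank)
        hi = min(len(vec), center + flank)
        if hi > lo:
            means[i] = float(vec[lo:hi].mean())
    series = pd.Series(means, index=sites.index, name="mean_signal")
    aggregate = float(np.nanmean(means)) if len(means) and not np.isnan(means).all() else float("nan")
    return series, aggregate


def region_counts(track: BinTrack, regions: pd.DataFrame) -> np.ndarray:
    """Sum bin counts over each region (all bins overlapping the region)."""
    out = np.zeros(len(regions))
    bw = track.bin_width
    for i, (chrom, s, e) in enumerate(zip(regions["chrom"], regions["start"], regions["end"])):
        vec = track.counts.get(chrom)
        if vec is None:
            continue
        lo = int(s) // bw
        hi = int(np.ceil(int(e) / bw))
        out[i] = vec[lo:hi].sum()
    return out


def write_bedgraph(track: BinTrack, path: str | Path) -> None:
    """Write a bin track as 4-column bedGraph (one line per bin, zeros included)."""
    frame = track.bin_frame()
    frame.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path, genome: Genome, bin_width: int = DEFAULT_BIN_WIDTH) -> BinTrack:
    """Read a bin-aligned bedGraph back into a BinTrack (lossless round-trip)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "count"])
    counts = {c: np.zeros(n, dtype=np.int64) for c, n in genome.n_bins(bin_width).items()}
    for chrom, grp in df.groupby("chrom"):
        if chrom not in counts:
            raise ValueError(f"bedGraph chromosome {chrom!r} not in genome")
        idx = grp["start"].to_numpy() // bin_width
        counts[chrom][idx] = grp["count"].to_numpy()
    library_size = int(df["count"].sum())
    return BinTrack(bin_width, counts, library_size)
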