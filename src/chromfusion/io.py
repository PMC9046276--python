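"""Plain-text genomics formats: BED6, narrowPeak, gene/TSS tables.

Coordinates are 0-based half-open on disk and in memory.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
NARROWPEAK_COLUMNS = BED6_COLUMNS + ["signalValue", "pValue", "qValue", "peak"]
GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand"]


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    if "name" not in out.columns:
        out["name"] = [f"peak_{i}" for i in range(len(out))]
    if "score" not in out.columns:
        out["score"] = 0
    if "strand" not in out.columns:
        out["strand"] = "."
    out[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED6_COLUMNS)
    ncol = df.shape[1]
    if ncol >= 10:
        df.columns = NARROWPEAK_COLUMNS[:10] + list(range(10, ncol))
    else:
        df.columns = BED6_COLUMNS[:ncol]
    return df


def write_genes(genes: pd.DataFrame, path: str | Path) -> None:
    genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_genes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table {path}: missing columns {missing}")
    return df


def gene_bodies(genes: pd.DataFrame, body_length: int = 20000) -> pd.DataFrame:
    """Synthetic gene-body intervals extending from the TSS in strand direction."""
    starts = []
    ends = []
    for tss, strand in zip(genes["tss"], genes["strand"]):
        if strand == "-":
            starts.append(max(0, int(tss) - body_length))
            ends.append(int(tss) + 1)
        else:
            starts.append(int(tss))
            ends.append(int(tss) + body_length)
    return pd.DataFrame({"chrom": genes["chrom"], "start": starts, "end": ends}).reset_index(
        drop=True
    )
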