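"""Genome container: named chromosomes with lengths, plus chrom.sizes I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome names and lengths (bp)."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths length mismatch")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))

    def n_bins(self, bin_width: int) -> dict[str, int]:
        return {c: int(np.ceil(l / bin_width)) for c, l in self.sizes.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def write_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.sizes.items():
                fh.write(f"{name}\t{length}\n")

    @classmethod
    def read_chrom_sizes(cls, path: str | Path) -> "Genome":
        names: list[str] = []
        lengths: list[int] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                name, length = line.split("\t")[:2]
                names.append(name)
                lengths.append(int(length))
        return cls(tuple(names), tuple(lengths))
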