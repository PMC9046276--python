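import numpy as np
import pandas as pd
import pytest

import chromfusion as cf


@pytest.fixture(scope="session")
def demo_genome():
    return cf.make_genome(4, 3e6, seed=7)


@pytest.fixture(scope="session")
def demo_truth(demo_genome):
    return cf.make_truth(demo_genome, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def brute_force_overlaps(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Quadratic reference for >= 1 bp half-open overlap membership."""
    out = np.zeros(len(query), dtype=bool)
    subj = list(zip(subject["chrom"], subject["start"], subject["end"]))
    for i, (c, s, e) in enumerate(zip(query["chrom"], query["start"], query["end"])):
        out[i] = any(c == sc and s < se and ss < e for sc, ss, se in subj)
    return out


def brute_force_merge(df: pd.DataFrame, gap: int) -> set:
    """Fixed-point pairwise merging, independent of the sweep implementation."""
    items = {(c, int(s), int(e)) for c, s, e in zip(df["chrom"], df["start"], df["end"])}
    changed = True
    while changed:
        changed = False
        for a in list(items):
            for b in list(items):
                if a is b or a not in items or b not in items or a == b:
                    continue
                if a[0] == b[0] and b[1] - a[2] <= gap and a[1] - b[2] <= gap:
                    items.discard(a)
                    items.discard(b)
                    items.add((a[0], min(a[1], b[1]), max(a[2], b[2])))
                    changed = True
    return items


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=100_000, max_len=500):
    starts = rng.integers(0, span, n)
    lengths = rng.integers(1, max_len, n)
    return pd.DataFrame(
        {
            "chrom": rng.choice(chroms, n),
            "start": starts,
            "end": starts + lengths,
        }
    )
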