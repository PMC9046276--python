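"""Synthetic fixtures with planted ground truth.

Every downstream stage of the package is testable without any download:
this module generates small genomes, Poisson (optionally overdispersed)
IP/Input bin tracks with planted fold-enriched regions, replicate peak
calls with boundary jitter and dropout, HiChIP-style loops wired from
planted peaks to gene promoters, and gene/TSS annotations — together
with a machine-readable truth object that acts as the test oracle.

Default study conditions
------------------------
The default fixture models a scaled-down ChIP experiment: a 4 × 3 Mb
genome (30000 bins of 400 bp), IP background of 5 expected reads per
bin, ten planted 800-bp regions at 8-fold enrichment, and a deep pooled
Input control at 10× the IP depth (one deep Input shared across many
IPs is standard ChIP-seq practice, and the per-bin fold-change statistic
needs a well-measured denominator).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import Genome
from .intervals import merge_within, overlaps_any
from .io import read_bed, read_genes, write_bed, write_genes
from .loops import LOOP_COLUMNS, check_loops, read_loops, write_loops
from .peaks import tss_windows
from .tracks import DEFAULT_BIN_WIDTH, BinTrack, read_bedgraph, write_bedgraph


def make_genome(
    n_chroms: int, mean_length: float, seed: int, bin_width: int = DEFAULT_BIN_WIDTH
) -> Genome:
    """Deterministic genome with lengths spread around ``mean_length``.

    Chromosome lengths take evenly spaced factors in [0.8, 1.2] of the
    mean (a single chromosome gets exactly the mean), permuted by the
    seed, and are rounded to multiples of the bin width.
    """
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    if mean_length < 10 * bin_width:
        raise ValueError(f"mean_length must be >= 10x bin width ({10 * bin_width})")
    rng = np.random.default_rng(seed)
    if n_chroms == 1:
        factors = np.array([1.0])
    else:
        factors = rng.permutation(np.linspace(0.8, 1.2, n_chroms))
    lengths = np.maximum(np.round(mean_length * factors / bin_width), 10).astype(int) * bin_width
    names = tuple(f"chr{i + 1}" for i in range(n_chroms))
    return Genome(names, tuple(int(l) for l in lengths))


@dataclass
class SyntheticTruth:
    """Planted ground truth: enriched regions, condition effects, loop wiring.

    ``enriched_regions`` carries (chrom, start, end, fold) with fold > 1;
    ``condition_effects`` maps a condition name to a per-region IP-rate
    multiplier; ``planted_loops`` lists anchor pairs with their expected
    interaction counts; ``gene_models`` holds (gene_id, chrom, tss, strand).
    """

    enriched_regions: pd.DataFrame
    background_rate: float
    condition_effects: dict[str, np.ndarray] = field(default_factory=dict)
    planted_loops: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=LOOP_COLUMNS[:-1] + ["expected_count"]))
    gene_models: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["gene_id", "chrom", "tss", "strand"]))
    seed: int = 0

    def __post_init__(self) -> None:
        regions = self.enriched_regions
        if len(regions):
            if (regions["fold"] <= 1).any():
                raise ValueError("planted region folds must be > 1")
            merged = merge_within(regions[["chrom", "start", "end"]], gap=0)
            if len(merged) != len(regions):
                raise ValueError("planted regions must be non-overlapping")
        for cond, mult in self.condition_effects.items():
            if len(mult) != len(regions):
                raise ValueError(f"condition {cond!r}: multiplier length mismatch")

    def validate_against(self, genome: Genome) -> None:
        sizes = genome.sizes
        for _, r in self.enriched_regions.iterrows():
            if r["chrom"] not in sizes or r["end"] > sizes[r["chrom"]] or r["start"] < 0:
                raise ValueError(f"planted region outside genome: {tuple(r[:3])}")
        for _, l in self.planted_loops.iterrows():
            for w in (1, 2):
                chrom, end = l[f"chrom{w}"], l[f"end{w}"]
                if chrom not in sizes or end > sizes[chrom] or l[f"start{w}"] < 0:
                    raise ValueError("planted loop anchor outside genome")

    def region_bins(self, bin_width: int = DEFAULT_BIN_WIDTH) -> pd.DataFrame:
        """Planted regions as an interval frame (bin-resolution oracle)."""
        return self.enriched_regions[["chrom", "start", "end"]].reset_index(drop=True)


def make_truth(
    genome: Genome,
    n_regions: int = 10,
    region_width: int = 800,
    fold: float = 8.0,
    background_rate: float = 5.0,
    n_genes: int = 40,
    n_loops: int = 8,
    loop_expected_count: float = 50.0,
    anchor_width: int = 5000,
    condition_effects: dict[str, np.ndarray] | None = None,
    tss_fraction: float = 0.2,
    seed: int = 0,
) -> SyntheticTruth:
    """Plant non-overlapping enriched regions, genes, and promoter-wired loops.

    The first ``n_loops`` planted regions each get a loop to the promoter
    of a dedicated target gene placed 100–300 kb away on the same
    chromosome; the last ``tss_fraction`` of regions sit at the promoter
    of a gene (promoter-bound sites); remaining genes are scattered
    uniformly but never with a promoter inside a planted loop anchor, so
    the planted wiring is exactly the set of (loop → target gene) links.
    Anchors are ``anchor_width`` windows centered on the region / TSS;
    regions are at least 50 kb apart.
    """
    rng = np.random.default_rng(seed)
    bw = DEFAULT_BIN_WIDTH
    chroms = list(genome.chrom_names)
    sizes = genome.sizes
    # place regions on bin boundaries, non-overlapping, away from edges
    regions: list[tuple[str, int, int]] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    margin = anchor_width + 400_000
    attempts = 0
    while len(regions) < n_regions and attempts < 10000:
        attempts += 1
        chrom = chroms[rng.integers(len(chroms))]
        length = sizes[chrom]
        if length < 2 * margin + region_width:
            continue
        start = int(rng.integers(margin // bw, (length - margin - region_width) // bw)) * bw
        end = start + region_width
        sep = 50_000  # keep planted sites well apart so 5-kb anchors never straddle two
        if any(s < end + sep and start < e + sep for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        regions.append((chrom, start, end))
    if len(regions) < n_regions:
        raise ValueError("genome too small to place the requested regions")
    region_df = pd.DataFrame(regions, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"]
    ).reset_index(drop=True)
    region_df["fold"] = float(fold)

    # genes: one dedicated target per looped region, the rest scattered
    gene_rows = []
    loop_rows = []
    n_loops = min(n_loops, len(region_df))
    placed_tss: list[tuple[str, int]] = []

    def clashes(chrom: str, tss: int) -> bool:
        # keep the promoter anchor clear of every planted region and of
        # other loop promoters: anchor half-width + promoter flank + slack
        clearance = anchor_width + 2000
        near_region = (
            (region_df["chrom"] == chrom)
            & (region_df["start"] - clearance < tss)
            & (tss < region_df["end"] + clearance)
        ).any()
        near_tss = any(c == chrom and abs(t - tss) < clearance for c, t in placed_tss)
        return bool(near_region or near_tss)

    for i in range(n_loops):
        r = region_df.iloc[i]
        for _ in range(200):
            offset = int(rng.integers(100_000, 300_000))
            direction = 1 if rng.random() < 0.5 or r["start"] - offset < anchor_width else -1
            tss = int(r["start"]) + direction * offset
            tss = int(np.clip(tss, anchor_width, sizes[r["chrom"]] - anchor_width - 1))
            if not clashes(r["chrom"], tss):
                break
        else:
            raise ValueError("could not place a clear target promoter for a planted loop")
        placed_tss.append((r["chrom"], tss))
        gene_rows.append((f"target_{i}", r["chrom"], tss, "+" if direction > 0 else "-"))
        center = (int(r["start"]) + int(r["end"])) // 2
        a1 = (r["chrom"], center - anchor_width // 2, center + anchor_width // 2)
        a2 = (r["chrom"], tss - anchor_width // 2, tss + anchor_width // 2)
        if a1[1] > a2[1]:
            a1, a2 = a2, a1
        loop_rows.append(a1 + a2 + (loop_expected_count,))
    # promoter-bound planted sites: put a gene's TSS at the center of the
    # last tss_fraction of regions (these model fusion binding at promoters)
    n_tss = int(round(tss_fraction * len(region_df)))
    for k, i in enumerate(range(len(region_df) - n_tss, len(region_df))):
        r = region_df.iloc[i]
        center = (int(r["start"]) + int(r["end"])) // 2
        gene_rows.append((f"promoter_{k}", r["chrom"], center, "+"))
    loop_df = pd.DataFrame(
        loop_rows,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "expected_count"],
    )
    # scattered background genes: rejection-sample so no promoter falls
    # inside a planted loop anchor or a planted region
    anchor_frames = [region_df[["chrom", "start", "end"]]]
    for w in (1, 2):
        anchor_frames.append(
            loop_df[[f"chrom{w}", f"start{w}", f"end{w}"]].set_axis(
                ["chrom", "start", "end"], axis=1
            )
        )
    forbidden = pd.concat(anchor_frames, ignore_index=True)
    n_scatter = max(0, n_genes - len(gene_rows))
    placed = 0
    attempts = 0
    while placed < n_scatter and attempts < 10000:
        attempts += 1
        chrom = chroms[rng.integers(len(chroms))]
        tss = int(rng.integers(anchor_width, sizes[chrom] - anchor_width))
        promoter = pd.DataFrame(
            {"chrom": [chrom], "start": [max(0, tss - 1000)], "end": [tss + 1001]}
        )
        if len(forbidden) and overlaps_any(promoter, forbidden).any():
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append((f"gene_{placed}", chrom, tss, strand))
        placed += 1
    gene_df = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "tss", "strand"])
    truth = SyntheticTruth(
        enriched_regions=region_df,
        background_rate=float(background_rate),
        condition_effects=condition_effects or {},
        planted_loops=loop_df,
        gene_models=gene_df,
        seed=int(seed),
    )
    truth.validate_against(genome)
    return truth


def _bin_rates(
    genome: Genome, truth: SyntheticTruth, bin_width: int, condition: str | None
) -> dict[str, np.ndarray]:
    """Per-bin IP rate multipliers (1 outside regions, fold × effect inside)."""
    mult = {c: np.ones(n) for c, n in genome.n_bins(bin_width).items()}
    effects = truth.condition_effects.get(condition) if condition else None
    for i, r in truth.enriched_regions.iterrows():
        lo = int(r["start"]) // bin_width
        hi = int(np.ceil(int(r["end"]) / bin_width))
        factor = float(r["fold"]) * (float(effects[i]) if effects is not None else 1.0)
        mult[r["chrom"]][lo:hi] = factor
    return mult


def simulate_pair_tracks(
    genome: Genome,
    truth: SyntheticTruth,
    ip_depth: float = 1.0,
    input_depth: float = 10.0,
    seed: int = 0,
    bin_width: int = DEFAULT_BIN_WIDTH,
    condition: str | None = None,
    dispersion: float | None = None,
) -> tuple[BinTrack, BinTrack]:
    """Sample matched IP and Input bin tracks.

    Input bins ~ Poisson(background_rate × input_depth); IP bins ~
    Poisson(background_rate × ip_depth × fold-multiplier), where the
    multiplier is the planted fold (times the condition effect) inside
    planted regions and 1 elsewhere.  ``dispersion`` > 0 switches to a
    gamma-Poisson (negative binomial) mixture for stress tests.
    """
    if ip_depth <= 0 or input_depth <= 0:
        raise ValueError("depths must be positive")
    truth.validate_against(genome)
    rng = np.random.default_rng(seed)
    mult = _bin_rates(genome, truth, bin_width, condition)
    ip_counts = {}
    input_counts = {}
    for chrom, m in mult.items():
        ip_rate = truth.background_rate * ip_depth * m
        input_rate = np.full_like(m, truth.background_rate * input_depth)
        if dispersion and dispersion > 0:
            shape = 1.0 / dispersion
            ip_rate = rng.gamma(shape, ip_rate * dispersion)
            input_rate = rng.gamma(shape, input_rate * dispersion)
        ip_counts[chrom] = rng.poisson(ip_rate)
        input_counts[chrom] = rng.poisson(input_rate)
    ip = BinTrack(bin_width, ip_counts, int(sum(v.sum() for v in ip_counts.values())))
    inp = BinTrack(bin_width, input_counts, int(sum(v.sum() for v in input_counts.values())))
    return ip, inp


def simulate_peak_calls(
    truth: SyntheticTruth,
    genome: Genome,
    n_replicates: int = 4,
    jitter_sd: float = 25.0,
    dropout: float = 0.05,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Replicate candidate peak calls over the planted regions.

    Each replicate contains each planted region with probability
    1 − dropout; boundaries are perturbed by Gaussian jitter and clipped
    to the genome.
    """
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    sizes = genome.sizes
    replicates = []
    for _ in range(n_replicates):
        rows = []
        for _, r in truth.enriched_regions.iterrows():
            if rng.random() < dropout:
                continue
            s = int(r["start"]) + int(round(rng.normal(0, jitter_sd))) if jitter_sd else int(r["start"])
            e = int(r["end"]) + int(round(rng.normal(0, jitter_sd))) if jitter_sd else int(r["end"])
            s = max(0, min(s, sizes[r["chrom"]] - 1))
            e = max(s + 1, min(e, sizes[r["chrom"]]))
            rows.append((r["chrom"], s, e))
        replicates.append(
            pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
                ["chrom", "start"]
            ).reset_index(drop=True)
        )
    return replicates


def simulate_loops(
    truth: SyntheticTruth,
    genome: Genome,
    n_noise_loops: int = 20,
    seed: int = 0,
    anchor_width: int = 5000,
    noise_count_rate: float = 3.0,
    avoid_planted: bool = True,
) -> pd.DataFrame:
    """Emit planted loops plus background noise loops.

    Planted loops get counts ~ Poisson(expected_count).  Noise loops
    connect random same-chromosome anchor pairs with counts ~
    Poisson(``noise_count_rate``); with ``avoid_planted`` their anchors
    steer clear of planted enriched regions and gene promoters, so they
    represent background contacts outside the planted regulatory wiring.
    """
    if truth.gene_models.empty and not len(truth.planted_loops):
        raise ValueError("truth must carry gene models or planted loops")
    rng = np.random.default_rng(seed)
    rows = []
    for _, l in truth.planted_loops.iterrows():
        count = int(rng.poisson(float(l["expected_count"])))
        rows.append(
            (l["chrom1"], int(l["start1"]), int(l["end1"]),
             l["chrom2"], int(l["start2"]), int(l["end2"]), count, True)
        )
    forbidden = pd.concat(
        [
            truth.enriched_regions[["chrom", "start", "end"]],
            tss_windows(truth.gene_models, flank=1000)[["chrom", "start", "end"]]
            if len(truth.gene_models)
            else pd.DataFrame(columns=["chrom", "start", "end"]),
        ],
        ignore_index=True,
    )
    sizes = genome.sizes
    chroms = list(genome.chrom_names)
    made = 0
    attempts = 0
    while made < n_noise_loops and attempts < 100 * max(n_noise_loops, 1):
        attempts += 1
        chrom = chroms[rng.integers(len(chroms))]
        if sizes[chrom] < 4 * anchor_width:
            continue
        c1 = int(rng.integers(anchor_width, sizes[chrom] - anchor_width))
        c2 = int(rng.integers(anchor_width, sizes[chrom] - anchor_width))
        if abs(c1 - c2) < 2 * anchor_width:
            continue
        anchors = pd.DataFrame(
            {
                "chrom": [chrom, chrom],
                "start": [c1 - anchor_width // 2, c2 - anchor_width // 2],
                "end": [c1 + anchor_width // 2, c2 + anchor_width // 2],
            }
        )
        if avoid_planted and len(forbidden) and overlaps_any(anchors, forbidden).any():
            continue
        if c1 > c2:
            c1, c2 = c2, c1
        count = int(rng.poisson(noise_count_rate))
        rows.append(
            (chrom, c1 - anchor_width // 2, c1 + anchor_width // 2,
             chrom, c2 - anchor_width // 2, c2 + anchor_width // 2, count, False)
        )
        made += 1
    loops = pd.DataFrame(rows, columns=LOOP_COLUMNS + ["planted"])
    return check_loops(loops)


def truth_to_json(truth: SyntheticTruth) -> dict:
    return {
        "enriched_regions": truth.enriched_regions.to_dict(orient="records"),
        "background_rate": truth.background_rate,
        "condition_effects": {k: list(map(float, v)) for k, v in truth.condition_effects.items()},
        "planted_loops": truth.planted_loops.to_dict(orient="records"),
        "gene_models": truth.gene_models.to_dict(orient="records"),
        "seed": truth.seed,
    }


def truth_from_json(obj: dict) -> SyntheticTruth:
    return SyntheticTruth(
        enriched_regions=pd.DataFrame(
            obj["enriched_regions"], columns=["chrom", "start", "end", "fold"]
        ),
        background_rate=float(obj["background_rate"]),
        condition_effects={k: np.array(v, dtype=float) for k, v in obj["condition_effects"].items()},
        planted_loops=pd.DataFrame(
            obj["planted_loops"],
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "expected_count"],
        ),
        gene_models=pd.DataFrame(obj["gene_models"], columns=["gene_id", "chrom", "tss", "strand"]),
        seed=int(obj["seed"]),
    )


def write_fixture(
    dir_path: str | Path,
    genome: Genome,
    truth: SyntheticTruth,
    tracks: dict[str, BinTrack] | None = None,
    peaks: dict[str, list[pd.DataFrame]] | None = None,
    loops: pd.DataFrame | None = None,
) -> dict:
    """Write a fixture directory in standard formats; returns the manifest.

    Emits chrom.sizes, one bedGraph per track, BED per peak replicate, a
    BEDPE-like loop file, a gene/TSS TSV, a truth JSON, and a
    manifest.json listing every file.  Round-trips losslessly through
    :func:`read_fixture`.
    """
    d = Path(dir_path)
    try:
        d.mkdir(parents=True, exist_ok=True)
        manifest: dict = {"files": []}

        def emit(name: str, writer) -> None:
            path = d / name
            writer(path)
            manifest["files"].append(name)

        emit("chrom.sizes", genome.write_chrom_sizes)
        emit("genes.tsv", lambda p: write_genes(truth.gene_models, p))
        emit("truth.json", lambda p: Path(p).write_text(json.dumps(truth_to_json(truth), indent=1)))
        for name, track in (tracks or {}).items():
            emit(f"{name}.bedgraph", lambda p, t=track: write_bedgraph(t, p))
            manifest.setdefault("tracks", {})[name] = {
                "bin_width": track.bin_width,
                "library_size": track.library_size,
            }
        for name, reps in (peaks or {}).items():
            for i, rep in enumerate(reps):
                emit(f"{name}_rep{i + 1}.bed", lambda p, r=rep: write_bed(r, p))
            manifest.setdefault("peaks", {})[name] = len(reps)
        if loops is not None:
            emit("loops.bedpe", lambda p: write_loops(loops, p))
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
        manifest["files"].append("manifest.json")
        return manifest
    except OSError as exc:
        raise OSError(f"writing fixture under {d}: {exc}") from exc


def read_fixture(dir_path: str | Path) -> dict:
    """Read a fixture directory back into in-memory objects."""
    d = Path(dir_path)
    manifest = json.loads((d / "manifest.json").read_text())
    genome = Genome.read_chrom_sizes(d / "chrom.sizes")
    truth = truth_from_json(json.loads((d / "truth.json").read_text()))
    tracks = {}
    for name, meta in manifest.get("tracks", {}).items():
        tracks[name] = read_bedgraph(d / f"{name}.bedgraph", genome, meta["bin_width"])
    peaks = {}
    for name, n_reps in manifest.get("peaks", {}).items():
        peaks[name] = [
            read_bed(d / f"{name}_rep{i + 1}.bed")[["chrom", "start", "end"]]
            for i in range(n_reps)
        ]
    loops = read_loops(d / "loops.bedpe") if (d / "loops.bedpe").exists() else None
    return {
        "genome": genome,
        "truth": truth,
        "tracks": tracks,
        "peaks": peaks,
        "loops": loops,
        "manifest": manifest,
    }
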