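"""Read processing and the quantile-stratified Z-score enrichment caller."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import chromfusion as cf
from chromfusion.enrichment import enriched_regions, gate_candidate_peaks
from chromfusion.genome import Genome
from chromfusion.tracks import BinTrack, region_counts

from conftest import brute_force_overlaps


def reads(rows, strand=True):
    cols = ["chrom", "start", "end", "strand"] if strand else ["chrom", "start", "end"]
    return pd.DataFrame(rows, columns=cols)


class TestCapRedundantReads:
    def test_cap_at_three(self):
        r = reads([("chr1", 10, 60, "+")] * 5)
        assert len(cf.cap_redundant_reads(r)) == 3

    def test_distinct_untouched(self):
        r = reads([("chr1", i, i + 50, "+") for i in range(10)])
        pd.testing.assert_frame_equal(cf.cap_redundant_reads(r), r)

    def test_below_cap_kept(self):
        r = reads([("chr1", 10, 60, "+")] * 2)
        assert len(cf.cap_redundant_reads(r)) == 2

    def test_strand_distinguishes_duplicates(self):
        r = reads([("chr1", 10, 60, "+")] * 3 + [("chr1", 10, 60, "-")] * 3)
        assert len(cf.cap_redundant_reads(r)) == 6

    def test_stable_order(self):
        r = reads([("chr2", 5, 10, "+"), ("chr1", 10, 60, "+"), ("chr1", 10, 60, "+")])
        out = cf.cap_redundant_reads(r)
        assert out.iloc[0]["chrom"] == "chr2"


class TestShiftAtacReads:
    def test_plus_strand_offset(self):
        out = cf.shift_atac_reads(reads([("chr1", 100, 150, "+")]))
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (104, 154)

    def test_minus_strand_offset(self):
        out = cf.shift_atac_reads(reads([("chr1", 150, 200, "-")]))
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (145, 195)

    def test_clip_at_zero(self):
        out = cf.shift_atac_reads(reads([("chr1", 0, 50, "-")]))
        assert out.iloc[0]["start"] == 0 and out.iloc[0]["end"] == 50

    def test_unstranded_rejected(self):
        with pytest.raises(ValueError):
            cf.shift_atac_reads(reads([("chr1", 0, 50)], strand=False))


class TestCoverageTrack:
    def test_fragment_extension(self):
        g = Genome(("chr1",), (1000,))
        cov = cf.make_coverage_track(reads([("chr1", 100, 150, "+")]), g)
        assert cov["chr1"][100:400].min() == 1
        assert cov["chr1"][:100].max() == 0 and cov["chr1"][400:].max() == 0

    def test_minus_strand_extends_upstream(self):
        g = Genome(("chr1",), (1000,))
        cov = cf.make_coverage_track(reads([("chr1", 500, 550, "-")]), g)
        assert cov["chr1"][250:550].min() == 1 and cov["chr1"][550:].max() == 0

    def test_cpm_scaling(self):
        g = Genome(("chr1",), (1000,))
        r = reads([("chr1", 0, 300, "+"), ("chr1", 0, 300, "+")])
        raw = cf.make_coverage_track(r, g)
        cpm = cf.make_coverage_track(r, g, normalize="CPM")
        np.testing.assert_allclose(cpm["chr1"], raw["chr1"] * 1e6 / 2)

    def test_stacked_reads_are_additive(self):
        g = Genome(("chr1",), (1000,))
        cov = cf.make_coverage_track(reads([("chr1", 0, 50, "+"), ("chr1", 100, 150, "+")]), g)
        assert cov["chr1"][120] == 2  # both fragments cover [100, 300)


class TestBinCounts:
    def test_boundary_convention(self):
        g = Genome(("chr1",), (4000,))
        track = cf.bin_counts(reads([("chr1", 399, 449, "+"), ("chr1", 400, 450, "+")]), g)
        assert track.counts["chr1"][0] == 1 and track.counts["chr1"][1] == 1

    def test_minus_strand_uses_five_prime(self):
        g = Genome(("chr1",), (4000,))
        track = cf.bin_counts(reads([("chr1", 350, 401, "-")]), g)
        assert track.counts["chr1"][1] == 1  # 5' at end-1 = 400

    def test_empty_reads(self):
        g = Genome(("chr1",), (4000,))
        track = cf.bin_counts(reads([]), g)
        assert track.flat().sum() == 0 and track.library_size == 0

    def test_unknown_chrom_rejected_with_count(self):
        g = Genome(("chr1",), (4000,))
        with pytest.warns(UserWarning, match="rejected 1"):
            track = cf.bin_counts(reads([("chr1", 0, 50, "+"), ("chrX", 0, 50, "+")]), g)
        assert track.library_size == 1

    def test_uniform_reads_spread_evenly(self, rng):
        g = Genome(("chr1",), (4000,))
        starts = rng.integers(0, 4000, 1000)
        r = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 1, "strand": "+"})
        track = cf.bin_counts(r, g)
        assert track.library_size == 1000
        assert np.all(np.abs(track.counts["chr1"] - 100) < 40)


def single_quantile_tracks():
    """The hand-computed example: 7 bins IP=Input=8, one bin IP=64, pseudo 1."""
    g = Genome(("chr1",), (3200,))
    ip = BinTrack(400, {"chr1": np.array([8] * 7 + [64])}, 120)
    inp = BinTrack(400, {"chr1": np.array([8] * 8)}, 64)
    return ip, inp


class TestCallEnrichedBins:
    def test_worked_example_z_and_bh(self):
        ip, inp = single_quantile_tracks()
        res = cf.call_enriched_bins(ip, inp, n_quantiles=1)
        hot = res.iloc[-1]
        assert hot["fold_change"] == pytest.approx(np.log2(65) - np.log2(9), abs=1e-9)
        assert hot["z"] == pytest.approx(2.4749, abs=1e-3)
        assert hot["fdr"] == pytest.approx(0.0533, abs=1e-3)
        assert not hot["enriched"]  # not significant at FDR 0.001

    def test_null_identity(self):
        g = Genome(("chr1",), (400 * 50,))
        counts = np.arange(50) % 7 + 1
        ip = BinTrack(400, {"chr1": counts.copy()}, int(counts.sum()))
        inp = BinTrack(400, {"chr1": counts.copy()}, int(counts.sum()))
        res = cf.call_enriched_bins(ip, inp)
        assert (res["fold_change"] == 0).all()
        assert not res["enriched"].any()

    def test_quantile_partition_and_standardization(self, demo_genome, demo_truth):
        ip, inp = cf.simulate_pair_tracks(demo_genome, demo_truth, seed=1)
        res = cf.call_enriched_bins(ip, inp, n_quantiles=10)
        sizes = res["quantile"].value_counts()
        assert sorted(sizes.index) == list(range(10))
        assert sizes.max() - sizes.min() <= 1
        for _, grp in res.groupby("quantile"):
            if grp["z"].std(ddof=1) > 0:
                assert abs(grp["z"].mean()) < 1e-9
                assert abs(grp["z"].std(ddof=1) - 1) < 1e-9

    def test_z_monotone_in_ip_count(self):
        # raising one bin's IP count (quantile membership held fixed via
        # n_quantiles=1) never decreases that bin's Z
        g = Genome(("chr1",), (3200,))
        inp = BinTrack(400, {"chr1": np.array([8] * 8)}, 64)
        last_z = -np.inf
        for hot in (8, 16, 32, 64, 128):
            ip = BinTrack(400, {"chr1": np.array([8] * 7 + [hot])}, 56 + hot)
            res = cf.call_enriched_bins(ip, inp, n_quantiles=1)
            z = res["z"].iloc[-1]
            assert z >= last_z - 1e-12
            last_z = z

    def test_zero_sd_quantile_gives_zero_z(self):
        ip = BinTrack(400, {"chr1": np.array([5] * 8)}, 40)
        inp = BinTrack(400, {"chr1": np.array([3] * 8)}, 24)
        res = cf.call_enriched_bins(ip, inp, n_quantiles=1)
        assert (res["z"] == 0).all()

    def test_mismatched_tracks_rejected(self):
        ip = BinTrack(400, {"chr1": np.zeros(8, dtype=int)}, 0)
        inp = BinTrack(200, {"chr1": np.zeros(8, dtype=int)}, 0)
        with pytest.raises(ValueError):
            cf.call_enriched_bins(ip, inp)

    def test_recovers_planted_regions(self, demo_genome, demo_truth):
        ip, inp = cf.simulate_pair_tracks(demo_genome, demo_truth, seed=7)
        res = cf.call_enriched_bins(ip, inp)
        planted_bins = region_counts(
            BinTrack(400, {c: res.loc[res["chrom"] == c, "enriched"].to_numpy().astype(int) for c in demo_genome.chrom_names}, 0),
            demo_truth.region_bins(),
        )
        # every planted 2-bin region has at least one flagged bin
        assert (planted_bins >= 1).all()
        background_rate = res["enriched"].mean()
        assert background_rate <= 0.005


class TestGateCandidatePeaks:
    def _enrichment(self):
        ip = BinTrack(400, {"chr1": np.array([5, 5, 80, 5, 5, 5, 5, 5, 5, 5] * 5)}, 600)
        inp = BinTrack(400, {"chr1": np.array([5] * 50)}, 250)
        return cf.call_enriched_bins(ip, inp, n_quantiles=1, fdr_threshold=0.05)

    def test_overlapping_candidate_kept(self):
        enr = self._enrichment()
        assert enr["enriched"].any()
        cands = pd.DataFrame({"chrom": ["chr1"], "start": [900], "end": [1000]})
        assert len(gate_candidate_peaks(cands, enr)) == 1

    def test_non_overlapping_candidate_dropped(self):
        enr = self._enrichment()
        cands = pd.DataFrame({"chrom": ["chr1"], "start": [1300], "end": [1500]})
        assert len(gate_candidate_peaks(cands, enr)) == 0

    def test_abutting_candidate_dropped(self):
        enr = self._enrichment()
        flagged = enr.loc[enr["enriched"]].iloc[0]
        cands = pd.DataFrame(
            {"chrom": [flagged["chrom"]], "start": [flagged["end"]], "end": [flagged["end"] + 100]}
        )
        assert len(gate_candidate_peaks(cands, enr)) == 0

    def test_matches_brute_force(self, rng):
        enr = self._enrichment()
        starts = rng.integers(0, 20_000, 200)
        cands = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + rng.integers(50, 800, 200)}
        )
        got = gate_candidate_peaks(cands, enr)
        expected = brute_force_overlaps(cands, enr.loc[enr["enriched"], ["chrom", "start", "end"]])
        assert len(got) == expected.sum()


class TestMeanSignalProfile:
    def test_constant_track(self):
        track = {"chr1": np.full(10_000, 3.0)}
        sites = pd.DataFrame({"chrom": ["chr1"] * 3, "start": [1000, 4000, 8000],
                              "end": [1100, 4100, 8100]})
        per_site, agg = cf.mean_signal_profile(track, sites, flank=500)
        assert np.allclose(per_site, 3.0) and agg == pytest.approx(3.0)

    def test_area_arithmetic(self):
        track = {"chr1": np.zeros(10_000)}
        track["chr1"][4750:5250] = 10.0  # central 500 bp of a site centered at 5000
        sites = pd.DataFrame({"chrom": ["chr1"], "start": [4900], "end": [5100]})
        per_site, agg = cf.mean_signal_profile(track, sites, flank=500)
        assert agg == pytest.approx(5.0)

    def test_empty_sites(self):
        per_site, agg = cf.mean_signal_profile({"chr1": np.zeros(100)}, pd.DataFrame(columns=["chrom", "start", "end"]))
        assert len(per_site) == 0 and np.isnan(agg)

    def test_edge_clipping_uses_effective_width(self):
        track = {"chr1": np.full(10_000, 2.0)}
        sites = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        per_site, _ = cf.mean_signal_profile(track, sites, flank=500)
        assert per_site.iloc[0] == pytest.approx(2.0)  # clipped window, same mean
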