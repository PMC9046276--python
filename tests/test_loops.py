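"""Loop filtering, EA classification, target genes, normalization, statistics."""

import numpy as np
import pandas as pd
import pytest

import chromfusion as cf
from chromfusion.loops import LOOP_COLUMNS, check_loops


def loop_table(rows):
    return check_loops(pd.DataFrame(rows, columns=LOOP_COLUMNS))


SIMPLE = [
    ("chr1", 0, 5000, "chr1", 100_000, 105_000, 6),
    ("chr1", 0, 5000, "chr1", 200_000, 205_000, 5),
    ("chr2", 0, 5000, "chr2", 50_000, 55_000, 100),
]


class TestCheckLoops:
    def test_interchromosomal_rejected_with_report(self):
        rows = SIMPLE + [("chr1", 0, 5000, "chr2", 0, 5000, 10)]
        with pytest.warns(UserWarning, match="1 inter-chromosomal"):
            loops = check_loops(pd.DataFrame(rows, columns=LOOP_COLUMNS))
        assert len(loops) == 3

    def test_anchor_order_canonicalized_and_length(self):
        loops = loop_table([("chr1", 100_000, 105_000, "chr1", 0, 5000, 7)])
        assert loops["start1"].iloc[0] == 0
        assert loops["length"].iloc[0] == 100_000  # midpoint distance


class TestFilterLoops:
    def test_strictly_greater_than(self):
        kept = cf.filter_loops(loop_table(SIMPLE), min_count=5)
        assert list(kept["count"]) == [6, 100]

    def test_empty_and_all_kept(self):
        assert len(cf.filter_loops(loop_table([]), 5)) == 0
        high = loop_table([r[:6] + (100,) for r in SIMPLE])
        assert len(cf.filter_loops(high, 5)) == 3


class TestClassifyLoops:
    peaks = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [2000]})

    def test_anchor1_overlap(self):
        out = cf.classify_loops(loop_table(SIMPLE[:2]), self.peaks)
        assert out["ea_associated"].all()

    def test_no_overlap(self):
        out = cf.classify_loops(loop_table([SIMPLE[2]]), self.peaks)
        assert not out["ea_associated"].any()

    def test_partition_complete(self):
        out = cf.classify_loops(loop_table(SIMPLE), self.peaks)
        assert out["ea_associated"].isin([True, False]).all()
        assert len(out) == 3


class TestAssignTargetGenes:
    genes = pd.DataFrame(
        {
            "gene_id": ["near", "far", "second"],
            "chrom": ["chr1", "chr1", "chr1"],
            "tss": [10_000, 900_000, 103_000],
            "strand": ["+", "+", "+"],
        }
    )

    def test_promoter_anchor_overlap(self):
        loops = loop_table([("chr1", 10_500, 15_500, "chr1", 100_000, 105_000, 10)])
        out = cf.assign_target_genes(loops, self.genes)
        assert set(out["gene_id"]) == {"near", "second"}

    def test_distant_gene_excluded(self):
        loops = loop_table([("chr1", 200_000, 205_000, "chr1", 400_000, 405_000, 10)])
        assert len(cf.assign_target_genes(loops, self.genes)) == 0

    def test_matches_brute_force_triple_loop(self, rng):
        starts = rng.integers(0, 1_000_000, 60)
        loops = loop_table(
            [
                ("chr1", int(s), int(s) + 5000, "chr1", int(s) + 50_000, int(s) + 55_000,
                 int(rng.integers(6, 50)))
                for s in starts
            ]
        )
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(80)],
                "chrom": "chr1",
                "tss": rng.integers(0, 1_100_000, 80),
                "strand": "+",
            }
        )
        got = set(
            zip(*cf.assign_target_genes(loops, genes)[["gene_id", "loop_id"]].to_numpy().T)
        )
        expected = set()
        for gi, tss in zip(genes["gene_id"], genes["tss"]):
            p_lo, p_hi = max(0, tss - 1000), tss + 1001
            for li in range(len(loops)):
                for w in (1, 2):
                    a_lo, a_hi = loops[f"start{w}"].iloc[li], loops[f"end{w}"].iloc[li]
                    if p_lo < a_hi and a_lo < p_hi:
                        expected.add((gi, li))
        assert got == expected


class TestNormalizeLoopCounts:
    def test_identical_conditions_unit_factors(self):
        a = np.array([10.0, 20.0, 30.0])
        na, nb, sf = cf.normalize_loop_counts(a, a)
        assert sf["a"] == pytest.approx(1.0) and sf["b"] == pytest.approx(1.0)

    def test_doubled_condition(self):
        a = np.array([10.0, 20.0, 30.0])
        na, nb, sf = cf.normalize_loop_counts(a, 2 * a)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)
        np.testing.assert_allclose(na, nb)

    def test_scaling_invariance_of_normalized_ratios(self):
        # depth is a nuisance: scaling one condition by c moves the factor
        # ratio by c and leaves every normalized fold change unchanged
        rng = np.random.default_rng(5)
        a = rng.poisson(20, 100).astype(float) + 1
        b = rng.poisson(20, 100).astype(float) + 1
        na1, nb1, sf1 = cf.normalize_loop_counts(a, b)
        na2, nb2, sf2 = cf.normalize_loop_counts(a, 3 * b)
        assert (sf2["b"] / sf2["a"]) / (sf1["b"] / sf1["a"]) == pytest.approx(3.0)
        np.testing.assert_allclose(nb1 / na1, nb2 / na2)

    def test_single_shared_loop(self):
        na, nb, sf = cf.normalize_loop_counts([4.0], [16.0])
        assert sf["a"] == pytest.approx(0.5) and sf["b"] == pytest.approx(2.0)

    def test_no_common_nonzero_rejected(self):
        with pytest.raises(ValueError):
            cf.normalize_loop_counts([0.0, 5.0], [3.0, 0.0])


class TestDifferentialLoops:
    def test_pseudo_counted_ratios(self):
        out = cf.differential_loops([10.0, 10.0], [25.0, 12.0])
        assert list(out["direction"]) == ["increased", "stable"]  # 26/11 >= 2; 13/11 < 2

    def test_decreased_symmetric(self):
        out = cf.differential_loops([25.0], [10.0])
        assert out["direction"].iloc[0] == "decreased"

    def test_identical_counts_all_stable(self):
        out = cf.differential_loops([5.0, 50.0], [5.0, 50.0])
        assert (out["direction"] == "stable").all()


class TestLoopStats:
    def anchors(self, cls_a=3, cls_b=3):
        starts = np.arange(cls_a + cls_b) * 100_000
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": starts,
                "end": starts + 5000,
                "class": ["EA"] * cls_a + ["nonEA"] * cls_b,
            }
        )

    def loops_per_anchor(self, anchors, per_anchor):
        rows = []
        for _, a in anchors.iterrows():
            for k in range(per_anchor[a["class"]]):
                partner = int(a["start"]) + 1_000_000 + 10_000 * k
                rows.append(
                    (a["chrom"], int(a["start"]), int(a["end"]),
                     a["chrom"], partner, partner + 5000, 10)
                )
        return loop_table(rows)

    def test_identical_classes_p_one(self):
        anchors = self.anchors()
        loops = self.loops_per_anchor(anchors, {"EA": 2, "nonEA": 2})
        out = cf.loop_stats(loops, anchors)
        assert out["welch_t"]["n_loops"]["p"] == pytest.approx(1.0)

    def test_medians_reflect_burden(self):
        anchors = self.anchors()
        loops = self.loops_per_anchor(anchors, {"EA": 8, "nonEA": 2})
        out = cf.loop_stats(loops, anchors)
        assert out["classes"]["EA"]["loops_per_anchor"]["median"] == 8
        assert out["classes"]["nonEA"]["loops_per_anchor"]["median"] == 2
        assert out["welch_t"]["n_loops"]["p"] < 0.05

    def test_small_class_skips_test(self):
        anchors = self.anchors(cls_a=1, cls_b=3)
        loops = self.loops_per_anchor(anchors, {"EA": 2, "nonEA": 2})
        out = cf.loop_stats(loops, anchors)
        assert out["welch_t"] is None and "fewer than 2 anchors" in out["test_skipped_reason"]

    def test_planted_ea_burden(self, demo_genome, demo_truth):
        loops = cf.simulate_loops(demo_truth, demo_genome, n_noise_loops=30, seed=2)
        kept = cf.filter_loops(loops, 5)
        regions = demo_truth.region_bins()
        anchor1 = kept[["chrom1", "start1", "end1"]].set_axis(["chrom", "start", "end"], axis=1)
        from chromfusion.intervals import overlaps_any

        cls = np.where(overlaps_any(anchor1, regions), "EA", "nonEA")
        anchors = anchor1.drop_duplicates().reset_index(drop=True)
        anchors["class"] = np.where(overlaps_any(anchors, regions), "EA", "nonEA")
        if (anchors["class"] == "EA").sum() >= 2 and (anchors["class"] == "nonEA").sum() >= 2:
            out = cf.loop_stats(kept, anchors)
            assert (
                out["classes"]["EA"]["counts_per_anchor"]["median"]
                >= out["classes"]["nonEA"]["counts_per_anchor"]["median"]
            )


class TestIntersectTargetsWithDeg:
    deg = pd.DataFrame(
        {
            "gene": ["a", "b", "c", "d"],
            "log2fc": [-1.0, np.log2(1.4), 2.0, -3.0],
            "adj_p": [0.01, 0.001, 0.2, 0.04],
        }
    )

    def test_split_by_sign(self):
        out = cf.intersect_targets_with_deg(["a", "b", "c", "d", "zz"], self.deg)
        assert out["down"] == ["a", "d"]  # |fold| 2 and 8, both significant
        assert out["up"] == []            # gene c fails padj
        assert out["n_untested"] == 1     # zz absent from the table

    def test_small_fold_excluded(self):
        out = cf.intersect_targets_with_deg(["b"], self.deg)
        assert out["down"] == [] and out["up"] == []

    def test_malformed_table_rejected(self):
        with pytest.raises(ValueError):
            cf.intersect_targets_with_deg(["a"], pd.DataFrame({"gene": ["a"]}))
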