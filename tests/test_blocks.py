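import numpy as np
import pandas as pd
import pytest

from enhmeth.blocks import (
    aggregate_blocks,
    block_beta,
    classify_block_context,
    classify_cgi_context,
)
from enhmeth.core_io import BetaMatrix, GenomicInterval


def make_annotation(positions, chrom="chr1"):
    return pd.DataFrame(
        {
            "probe_id": [f"cg{i:04d}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": positions,
            "design_type": "II",
        }
    )


def brute_force_chain(positions, max_gap=500):
    """O(n^2)-style oracle: clusters = connected components of the
    'within max_gap of the previous sorted position' relation."""
    pos = sorted(positions)
    clusters = [[pos[0]]]
    for p in pos[1:]:
        if p - clusters[-1][-1] <= max_gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters


class TestAggregateBlocks:
    def test_chaining_rule_example(self):
        blocks = aggregate_blocks(make_annotation([100, 550, 700, 1300]))
        assert [b.n_probes for b in blocks] == [3, 1]
        assert blocks[0].interval.start == 100 and blocks[0].interval.end == 701
        assert blocks[1].probe_ids == ["cg0003"]

    def test_single_probe(self):
        (b,) = aggregate_blocks(make_annotation([42]))
        assert b.n_probes == 1 and (b.interval.start, b.interval.end) == (42, 43)

    def test_boundary_gap_inclusive(self):
        # gap of exactly 500 chains, 501 splits
        assert len(aggregate_blocks(make_annotation([0, 500]))) == 1
        assert len(aggregate_blocks(make_annotation([0, 501]))) == 2

    def test_matches_bruteforce_oracle(self, rng):
        positions = np.unique(rng.integers(0, 2_000_000, size=10_000))
        blocks = aggregate_blocks(make_annotation(positions))
        oracle = brute_force_chain(positions)
        assert [b.n_probes for b in blocks] == [len(c) for c in oracle]
        assert [b.interval.start for b in blocks] == [c[0] for c in oracle]

    def test_partition_property(self, rng):
        positions = np.unique(rng.integers(0, 500_000, size=2_000))
        ann = make_annotation(positions)
        blocks = aggregate_blocks(ann)
        all_probes = [p for b in blocks for p in b.probe_ids]
        assert sorted(all_probes) == sorted(ann["probe_id"])
        assert len(set(all_probes)) == len(all_probes)

    def test_order_independence(self, rng):
        positions = np.unique(rng.integers(0, 100_000, size=500))
        ann = make_annotation(positions)
        shuffled = ann.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = aggregate_blocks(ann)
        b = aggregate_blocks(shuffled)
        assert [x.probe_ids for x in a] == [y.probe_ids for y in b]

    def test_blocks_per_chromosome_nonoverlapping(self, rng):
        positions = np.unique(rng.integers(0, 100_000, size=300))
        blocks = aggregate_blocks(make_annotation(positions))
        for prev, nxt in zip(blocks, blocks[1:]):
            assert prev.interval.end <= nxt.interval.start

    def test_empty_input(self):
        assert aggregate_blocks(make_annotation([])) == []


class TestBlockBeta:
    def test_mean_of_members(self):
        ann = make_annotation([100, 200])
        blocks = aggregate_blocks(ann)
        m = BetaMatrix(pd.DataFrame({"S1": [0.2, 0.4]}, index=["cg0000", "cg0001"]))
        out = block_beta(m, blocks)
        assert out.values.iloc[0, 0] == pytest.approx(0.3)

    def test_single_probe_identity(self):
        ann = make_annotation([100])
        m = BetaMatrix(pd.DataFrame({"S1": [0.77]}, index=["cg0000"]))
        out = block_beta(m, aggregate_blocks(ann))
        assert out.values.iloc[0, 0] == 0.77

    def test_nan_excluded_and_all_nan_propagates(self):
        ann = make_annotation([100, 200])
        m = BetaMatrix(
            pd.DataFrame(
                {"S1": [0.2, np.nan], "S2": [np.nan, np.nan]},
                index=["cg0000", "cg0001"],
            )
        )
        out = block_beta(m, aggregate_blocks(ann))
        assert out.values.loc[:, "S1"].iloc[0] == pytest.approx(0.2)
        assert np.isnan(out.values.loc[:, "S2"].iloc[0])

    def test_matches_naive_reaggregation(self, rng):
        positions = np.unique(rng.integers(0, 300_000, size=400))
        ann = make_annotation(positions)
        blocks = aggregate_blocks(ann)
        vals = rng.uniform(0, 1, size=(len(positions), 4))
        m = BetaMatrix(
            pd.DataFrame(vals, index=ann["probe_id"].tolist(),
                         columns=list("ABCD"))
        )
        out = block_beta(m, blocks)
        for blk in blocks:
            expected = m.values.loc[blk.probe_ids].mean(axis=0)
            assert np.allclose(out.values.loc[blk.block_id], expected)


class TestContext:
    def test_tss_proximal_categories(self):
        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [10_000], "strand": ["+"]})
        cgi = []
        ann = make_annotation([9_850])  # 150 bp upstream of + TSS
        (blk,) = aggregate_blocks(ann)
        classify_block_context(blk, ann, tss, cgi)
        assert blk.gene_context == {"TSS200"}
        ann2 = make_annotation([9_100])  # 900 bp upstream
        (blk2,) = aggregate_blocks(ann2)
        classify_block_context(blk2, ann2, tss, cgi)
        assert blk2.gene_context == {"TSS1500"}

    def test_minus_strand_upstream(self):
        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [10_000], "strand": ["-"]})
        ann = make_annotation([10_150])  # 150 bp upstream on the - strand
        (blk,) = aggregate_blocks(ann)
        classify_block_context(blk, ann, tss, [])
        assert blk.gene_context == {"TSS200"}

    def test_intergenic_fallback(self):
        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [10_000], "strand": ["+"]})
        ann = make_annotation([500_000])
        (blk,) = aggregate_blocks(ann)
        classify_block_context(blk, ann, tss, [])
        assert blk.gene_context == {"Intergenic"}

    @pytest.mark.parametrize(
        "midpoint,expected",
        [
            (10_500, "Island"),
            (9_500, "N_Shore"),     # 500 bp left of the island edge
            (7_500, "N_Shelf"),     # 2,500 bp left
            (11_999, "S_Shore"),
            (13_500, "S_Shelf"),
            (20_000, "OpenSea"),
        ],
    )
    def test_cgi_bands(self, midpoint, expected):
        cgi = [GenomicInterval("chr1", 10_000, 11_000)]
        assert classify_cgi_context(midpoint, "chr1", cgi) == expected

    def test_cgi_context_exhaustive(self, rng):
        cgi = [GenomicInterval("chr1", 50_000, 52_000)]
        for pos in rng.integers(0, 100_000, size=200):
            ctx = classify_cgi_context(int(pos), "chr1", cgi)
            assert ctx in {"Island", "N_Shore", "N_Shelf", "S_Shore", "S_Shelf", "OpenSea"}
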