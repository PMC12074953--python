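import numpy as np
import pytest

from enhmeth.core_io import GenomicInterval
from enhmeth.enhancers import (
    EnhancerCalls,
    SignalPeak,
    associate_genes,
    call_super_enhancers,
    exclude_tss_proximal,
    overlap_fractions,
    subtract_background,
)
from enhmeth.blocks import GenomicBlock
from enhmeth.errors import InsufficientDataError


def make_peaks(signals, length=500):
    return [
        SignalPeak(GenomicInterval("chr1", 10_000 * i + 1, 10_000 * i + 1 + length),
                   s / length)
        for i, s in enumerate(signals)
    ]


class TestBackground:
    def test_simple_subtraction(self):
        peak = SignalPeak(GenomicInterval("chr1", 100, 200), 5.0)
        ctrl = [GenomicInterval("chr1", 0, 500, score=2.0)]
        (out,) = subtract_background([peak], ctrl)
        assert out.density == pytest.approx(3.0)

    def test_floor_at_zero(self):
        peak = SignalPeak(GenomicInterval("chr1", 100, 200), 1.0)
        ctrl = [GenomicInterval("chr1", 0, 500, score=9.0)]
        (out,) = subtract_background([peak], ctrl)
        assert out.density == 0.0

    def test_no_control_identity(self):
        peaks = make_peaks([1, 2, 3])
        out = subtract_background(peaks, None)
        assert [p.density for p in out] == [p.density for p in peaks]

    def test_partial_overlap_weighting(self):
        peak = SignalPeak(GenomicInterval("chr1", 100, 200), 5.0)
        ctrl = [GenomicInterval("chr1", 100, 150, score=4.0)]  # covers half
        (out,) = subtract_background([peak], ctrl)
        assert out.density == pytest.approx(5.0 - 2.0)


class TestTssExclusion:
    def test_examples(self):
        tss = [GenomicInterval("chr1", 10_000, 10_001)]
        removed = SignalPeak(GenomicInterval("chr1", 9_000, 9_500), 1.0)
        kept = SignalPeak(GenomicInterval("chr1", 20_000, 21_000), 1.0)
        out = exclude_tss_proximal([removed, kept], tss)
        assert [p.interval.start for p in out] == [20_000]

    def test_matches_bruteforce_oracle(self, rng):
        peaks = [
            SignalPeak(GenomicInterval("chr1", int(s), int(s) + int(l)), 1.0)
            for s, l in zip(
                rng.integers(0, 1_000_000, 300), rng.integers(100, 2000, 300)
            )
        ]
        tss = [
            GenomicInterval("chr1", int(t), int(t) + 1)
            for t in rng.integers(0, 1_000_000, 50)
        ]
        got = exclude_tss_proximal(peaks, tss, window=2000)
        oracle = [
            p
            for p in peaks
            if not any(
                p.interval.start <= t.start + 2000 and p.interval.end > t.start - 2000
                for t in tss
            )
        ]
        assert [(p.interval.start, p.interval.end) for p in got] == [
            (p.interval.start, p.interval.end) for p in oracle
        ]


class TestSuperEnhancerCalling:
    def test_quadratic_curve_half_super(self):
        n = 10_000
        sig = (np.arange(1, n + 1) / n) ** 2
        calls = call_super_enhancers(make_peaks(sig))
        assert calls.super_fraction == pytest.approx(0.5, abs=0.01)

    def test_linear_ramp_no_supers(self):
        calls = call_super_enhancers(make_peaks(np.arange(1.0, 1001.0)))
        assert calls.super == []

    def test_flat_signal_no_supers(self):
        calls = call_super_enhancers(make_peaks(np.full(100, 3.0)))
        assert calls.super == []

    def test_partition_and_signal_ordering(self, rng):
        sig = rng.pareto(2.0, size=500) + 0.1
        calls = call_super_enhancers(make_peaks(sig))
        assert len(calls.typical) + len(calls.super) == len(calls.ranked_peaks)
        if calls.super:
            assert min(p.total_signal for p in calls.super) >= max(
                p.total_signal for p in calls.typical
            )

    def test_duplication_stability(self):
        n = 2000
        sig = (np.arange(1, n + 1) / n) ** 2
        f1 = call_super_enhancers(make_peaks(sig)).super_fraction
        f2 = call_super_enhancers(make_peaks(np.repeat(sig, 2))).super_fraction
        assert abs(f1 - f2) <= 1.0 / n + 1e-9

    def test_too_few_peaks(self):
        with pytest.raises(InsufficientDataError):
            call_super_enhancers(make_peaks([1.0] * 5))


class TestGeneLinks:
    def _calls(self, intervals):
        peaks = [SignalPeak(iv, 1.0) for iv in intervals]
        return EnhancerCalls(peaks, len(peaks) - 1, 0.0, peaks, [])

    def test_distance_examples(self):
        calls = self._calls([GenomicInterval("chr1", 100_000, 101_000)])
        tss = [
            GenomicInterval("chr1", 130_000, 130_001, "+", "NEAR"),   # 29 kb away
            GenomicInterval("chr1", 160_000, 160_001, "+", "FAR"),    # 59 kb away
        ]
        links = associate_genes(calls, tss)
        assert links == {0: ["NEAR"]}

    def test_tss_inside_enhancer(self):
        calls = self._calls([GenomicInterval("chr1", 100_000, 101_000)])
        tss = [GenomicInterval("chr1", 100_500, 100_501, "+", "IN")]
        assert associate_genes(calls, tss) == {0: ["IN"]}

    def test_matches_bruteforce_oracle(self, rng):
        intervals = [
            GenomicInterval("chr1", int(s), int(s) + 1000)
            for s in sorted(rng.integers(0, 3_000_000, 100))
        ]
        calls = self._calls(intervals)
        tss = [
            GenomicInterval("chr1", int(t), int(t) + 1, "+", f"G{k}")
            for k, t in enumerate(rng.integers(0, 3_000_000, 200))
        ]
        links = associate_genes(calls, tss, max_dist=50_000)
        for rank, iv in enumerate(intervals):
            expected = sorted(
                t.name
                for t in tss
                if (
                    iv.start - 50_000 <= t.start < iv.end + 50_000
                    and (
                        t.start >= iv.start - 50_000
                        if t.start < iv.start
                        else t.start - iv.end <= 50_000
                    )
                )
            )
            assert links.get(rank, []) == expected


class TestOverlapFractions:
    def _blocks(self):
        return [
            GenomicBlock(f"b{i}", GenomicInterval("chr1", 1000 * i, 1000 * i + 500), [f"cg{i}"])
            for i in range(8)
        ]

    def test_fraction_example(self):
        blocks = self._blocks()
        regions = {"R": [GenomicInterval("chr1", 0, 100)]}  # covers b0 only
        out = overlap_fractions({"set": {"b0", "b1", "b2", "b3"}}, blocks, regions)
        assert out["fraction"].iloc[0] == pytest.approx(0.25)

    def test_whole_genome_region(self):
        blocks = self._blocks()
        regions = {"all": [GenomicInterval("chr1", 0, 10_000_000)]}
        out = overlap_fractions(
            {"a": {"b0"}, "b": {b.block_id for b in blocks}}, blocks, regions
        )
        assert (out["fraction"] == 1.0).all()

    def test_empty_set_rejected(self):
        with pytest.raises(InsufficientDataError):
            overlap_fractions({"s": set()}, self._blocks(), {"R": [GenomicInterval("chr1", 0, 1)]})
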