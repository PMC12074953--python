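"""Super-enhancer classification from ranked H3K27ac signal and region
overlap statistics.

Peaks carry a read density in rpm/bp (reads per million per base pair);
the quantity ranked is the total background-subtracted signal, density ×
peak length. After removing peaks within ±2000 bp of a transcription
start site, peaks are sorted by ascending total signal and both rank and
signal are rescaled to [0, 1]; super-enhancers are the peaks above the
point where the slope of this curve exceeds 1 and stays above 1 for the
rest of the curve (the geometric tangent rule of rank-ordering
approaches). Genes are linked to an enhancer when their TSS lies within
50 kb of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import GenomicBlock
from .core_io import GenomicInterval
from .errors import InsufficientDataError

TSS_WINDOW = 2000      # bp excluded around a TSS
LINK_DISTANCE = 50_000  # bp for enhancer-gene association


@dataclass
class SignalPeak:
    """An H3K27ac peak with background-subtracted density (rpm/bp, >= 0)."""

    interval: GenomicInterval
    density: float

    def __post_init__(self):
        if self.density < 0:
            raise ValueError("peak density must be >= 0 after background subtraction")

    @property
    def total_signal(self) -> float:
        return self.density * len(self.interval)


@dataclass
class EnhancerCalls:
    """Ranked peak set partitioned into typical and super-enhancers."""

    ranked_peaks: list[SignalPeak]        # ascending total_signal
    cutoff_index: int
    cutoff_signal: float
    typical: list[SignalPeak]
    super: list[SignalPeak]
    gene_links: dict[int, list[str]] = field(default_factory=dict)  # rank -> genes

    @property
    def super_fraction(self) -> float:
        return len(self.super) / len(self.ranked_peaks)


def peaks_from_intervals(intervals: list[GenomicInterval]) -> list[SignalPeak]:
    """Interpret scored intervals (bedGraph) as signal peaks."""
    return [
        SignalPeak(iv, iv.score if iv.score is not None else 0.0) for iv in intervals
    ]


def subtract_background(
    peaks: list[SignalPeak], control: list[GenomicInterval] | None
) -> list[SignalPeak]:
    """Per-peak density minus mean control density over the peak, floored at 0.

    Control density is averaged base-wise over the peak interval
    (uncovered bases contribute 0). Without a control this is the
    identity.
    """
    if control is None:
        return [SignalPeak(p.interval, p.density) for p in peaks]
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in control:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for p in peaks:
        covered = 0.0
        for iv in by_chrom.get(p.interval.chrom, ()):
            lo = max(iv.start, p.interval.start)
            hi = min(iv.end, p.interval.end)
            if hi > lo:
                covered += (hi - lo) * (iv.score if iv.score is not None else 0.0)
        mean_ctrl = covered / len(p.interval)
        out.append(SignalPeak(p.interval, max(0.0, p.density - mean_ctrl)))
    return out


def exclude_tss_proximal(
    peaks: list[SignalPeak],
    tss: list[GenomicInterval],
    window: int = TSS_WINDOW,
) -> list[SignalPeak]:
    """Drop peaks whose interval intersects [tss - window, tss + window].

    TSS position is the interval start (for point TSS rows start = pos).
    The exclusion window is closed at both ends.
    """
    by_chrom: dict[str, np.ndarray] = {}
    for iv in tss:
        by_chrom.setdefault(iv.chrom, [])
    for iv in tss:
        by_chrom[iv.chrom].append(iv.start)  # type: ignore[union-attr]
    by_chrom = {c: np.sort(np.asarray(v)) for c, v in by_chrom.items()}
    out = []
    for p in peaks:
        pos = by_chrom.get(p.interval.chrom)
        hit = False
        if pos is not None and len(pos):
            # peak [s, e) intersects [t-w, t+w]  <=>  s <= t+w and e > t-w
            lo = np.searchsorted(pos, p.interval.start - window, side="left")
            hi = np.searchsorted(pos, p.interval.end + window, side="left")
            for t in pos[lo:hi]:
                if p.interval.start <= t + window and p.interval.end > t - window:
                    hit = True
                    break
        if not hit:
            out.append(p)
    return out


def call_super_enhancers(
    peaks: list[SignalPeak], rank_by: str = "total_signal"
) -> EnhancerCalls:
    """Partition peaks into typical and super-enhancers by the slope-1 rule.

    Peaks are sorted ascending by ``rank_by`` (total_signal, or density);
    rank and signal are each min-max rescaled to [0, 1] and the slope at
    every interior point is taken by central finite difference. The cutoff
    is the first interior index from which the slope exceeds 1 and remains
    above 1 to the end; peaks strictly above the cutoff are
    super-enhancers. Exactly linear or constant curves yield none.
    """
    keyfun = {
        "total_signal": lambda p: p.total_signal,
        "density": lambda p: p.density,
    }[rank_by]
    positive = [p for p in peaks if keyfun(p) > 0]
    if len(positive) < 10:
        raise InsufficientDataError(
            f"super-enhancer calling needs >= 10 peaks with positive signal, "
            f"got {len(positive)}"
        )
    ranked = sorted(
        positive, key=lambda p: (keyfun(p), p.interval.chrom, p.interval.start)
    )
    n = len(ranked)
    y_raw = np.array([keyfun(p) for p in ranked], dtype=float)
    span = y_raw[-1] - y_raw[0]
    if span <= 0:  # flat curve
        return EnhancerCalls(ranked, n - 1, float(y_raw[-1]), list(ranked), [])
    x = np.arange(n, dtype=float) / (n - 1)
    y = (y_raw - y_raw[0]) / span
    slope = (y[2:] - y[:-2]) / (x[2:] - x[:-2])  # interior points 1..n-2
    above = slope > 1.0
    # first interior index from which slope stays > 1
    idx = None
    run_ok = True
    for i in range(len(above) - 1, -1, -1):
        run_ok = run_ok and above[i]
        if run_ok:
            idx = i + 1  # interior offset -> peak index
        if not run_ok:
            break
    if idx is None:
        return EnhancerCalls(ranked, n - 1, float(y_raw[-1]), list(ranked), [])
    cutoff_index = idx
    return EnhancerCalls(
        ranked_peaks=ranked,
        cutoff_index=cutoff_index,
        cutoff_signal=float(y_raw[cutoff_index]),
        typical=list(ranked[: cutoff_index + 1]),
        super=list(ranked[cutoff_index + 1 :]),
    )


def associate_genes(
    calls: EnhancerCalls,
    tss: list[GenomicInterval],
    max_dist: int = LINK_DISTANCE,
) -> dict[int, list[str]]:
    """Link genes to enhancers whose edge lies within ``max_dist`` of the TSS.

    ``tss`` intervals carry gene ids in ``name``; the TSS position is the
    interval start. Distance is 0 inside the enhancer, otherwise the gap
    to the nearest enhancer edge. Returns rank -> sorted gene list and
    stores it on ``calls``.
    """
    if not tss:
        raise InsufficientDataError("empty TSS track")
    links: dict[int, list[str]] = {}
    for rank, peak in enumerate(calls.ranked_peaks):
        iv = peak.interval
        genes = []
        for t in tss:
            if t.chrom != iv.chrom:
                continue
            pos = t.start
            if pos < iv.start:
                d = iv.start - pos
            elif pos >= iv.end:
                d = pos - iv.end
            else:
                d = 0
            if d <= max_dist:
                genes.append(t.name if t.name is not None else f"{t.chrom}:{t.start}")
        if genes:
            links[rank] = sorted(genes)
    calls.gene_links = links
    return links


def _block_hits_regions(block: GenomicBlock, regions_by_chrom) -> bool:
    starts, ends = regions_by_chrom.get(block.interval.chrom, (None, None))
    if starts is None:
        return False
    i = np.searchsorted(ends, block.interval.start, side="right")
    return bool(i < len(starts) and starts[i] < block.interval.end)


def _index_regions(regions: list[GenomicInterval]):
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[tuple[int, int]]] = {}
    for iv in regions:
        tmp.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, pairs in tmp.items():
        pairs.sort()
        starts = np.array([p[0] for p in pairs])
        ends = np.array([p[1] for p in pairs])
        # make ends non-decreasing for searchsorted on possibly nested intervals
        ends = np.maximum.accumulate(ends)
        by_chrom[chrom] = (starts, ends)
    return by_chrom


def overlap_fractions(
    block_sets: dict[str, set[str]],
    blocks: list[GenomicBlock],
    region_sets: dict[str, list[GenomicInterval]],
) -> pd.DataFrame:
    """Fraction of each block set overlapping each region set, with
    hypergeometric enrichment against the full block universe.

    A block counts as overlapping when its interval intersects at least
    one region. For every (block set, region set) pair a two-sided Fisher
    exact p compares the set to the universe of all given blocks.
    """
    if not block_sets or not blocks or not region_sets:
        raise InsufficientDataError("empty block set, block list or region set")
    block_by_id = {b.block_id: b for b in blocks}
    rows = []
    for rname, regions in region_sets.items():
        idx = _index_regions(regions)
        hit_ids = {b.block_id for b in blocks if _block_hits_regions(b, idx)}
        n_univ = len(blocks)
        k_univ = len(hit_ids)
        for sname, ids in block_sets.items():
            if not ids:
                raise InsufficientDataError(f"block set {sname!r} is empty")
            missing = set(ids) - set(block_by_id)
            if missing:
                raise InsufficientDataError(
                    f"block set {sname!r} has unknown blocks: {sorted(missing)[:5]}"
                )
            a = len(set(ids) & hit_ids)
            b = len(ids) - a
            c = k_univ - a
            d = n_univ - len(ids) - c
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append(
                {
                    "block_set": sname,
                    "region_set": rname,
                    "n_blocks": len(ids),
                    "n_overlap": a,
                    "fraction": a / len(ids),
                    "fraction_universe": k_univ / n_univ,
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)


def calls_to_frame(calls: EnhancerCalls) -> pd.DataFrame:
    """Ranked-curve table: rank, coordinates, density, total signal, class."""
    n = len(calls.ranked_peaks)
    rows = []
    for rank, p in enumerate(calls.ranked_peaks):
        rows.append(
            {
                "rank": rank,
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "density": p.density,
                "total_signal": p.total_signal,
                "class": "super" if rank > calls.cutoff_index else "typical",
                "genes": ";".join(calls.gene_links.get(rank, [])),
            }
        )
    return pd.DataFrame(rows)
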