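"""Aggregate array probes into genomic blocks and classify block context.

A genomic block is a maximal chain of probes on one chromosome in which
consecutive probes lie at most ``max_gap`` (default 500) bp apart —
single-linkage chaining, so block extent is unbounded while inter-probe
gaps stay small. Block methylation is the per-sample mean β over member
probes. Blocks are classified relative to transcription start sites
(TSS200 / TSS1500 / 5'UTR / first exon / body / 3'UTR / intergenic) and
relative to CpG islands (island, N/S shore at 0–2 kb, N/S shelf at
2–4 kb, open sea beyond).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    BetaMatrix,
    FeatureLevel,
    GenomicInterval,
    validate_probe_annotation,
)

logger = logging.getLogger(__name__)

SHORE_BP = 2000   # CGI shore: 0-2 kb from an island edge
SHELF_BP = 4000   # CGI shelf: 2-4 kb


@dataclass
class GenomicBlock:
    """A chained cluster of probes summarized as one methylation feature."""

    block_id: str
    interval: GenomicInterval
    probe_ids: list[str]
    gene_context: set[str] = field(default_factory=set)
    cgi_context: str | None = None

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def aggregate_blocks(annotation: pd.DataFrame, max_gap: int = 500) -> list[GenomicBlock]:
    """Chain probes within ``max_gap`` bp into blocks, per chromosome.

    A probe joins the current block iff its distance to the previous probe
    on the same chromosome is <= ``max_gap``. Block interval spans
    [first probe position, last probe position + 1). Output is sorted by
    (chrom, start) and independent of input row order.
    """
    if len(annotation) == 0:
        return []
    annotation = validate_probe_annotation(annotation)
    ordered = annotation.sort_values(
        ["chrom", "pos", "probe_id"], kind="mergesort"
    )
    blocks: list[GenomicBlock] = []
    counter = 0
    for chrom, sub in ordered.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        ids = sub["probe_id"].to_numpy()
        breaks = np.where(np.diff(pos) > max_gap)[0] + 1
        for seg_ids, seg_pos in zip(
            np.split(ids, breaks), np.split(pos, breaks)
        ):
            counter += 1
            blocks.append(
                GenomicBlock(
                    block_id=f"GB{counter:06d}",
                    interval=GenomicInterval(chrom, int(seg_pos[0]), int(seg_pos[-1]) + 1),
                    probe_ids=list(seg_ids),
                )
            )
    return blocks


def block_beta(matrix: BetaMatrix, blocks: list[GenomicBlock]) -> BetaMatrix:
    """Block-level matrix: per-sample mean β over member probes, NA-excluded.

    Probes referenced by a block but absent from the matrix are dropped with
    a warning; a block whose probes are all absent is dropped and logged.
    A block whose present probes are all-NA in a sample gets NA there.
    """
    present = set(matrix.row_ids)
    probe_to_block: dict[str, str] = {}
    kept_ids: list[str] = []
    n_missing = 0
    for blk in blocks:
        usable = [p for p in blk.probe_ids if p in present]
        n_missing += blk.n_probes - len(usable)
        if not usable:
            logger.warning("block %s has no probes in matrix; dropped", blk.block_id)
            continue
        kept_ids.append(blk.block_id)
        for p in usable:
            probe_to_block[p] = blk.block_id
    if n_missing:
        logger.warning("%d block probes absent from matrix", n_missing)
    sub = matrix.values.loc[list(probe_to_block)]
    grouped = sub.groupby([probe_to_block[p] for p in sub.index]).mean()
    grouped = grouped.loc[kept_ids]  # genomic order, not lexicographic
    grouped.index.name = "block_id"
    return BetaMatrix(grouped, FeatureLevel.block)


def _gene_context_for_position(
    chrom: str,
    pos: int,
    tss: pd.DataFrame,
    gene_model: pd.DataFrame | None,
) -> set[str]:
    """TSS-relative and gene-model categories hit by one probe position."""
    out: set[str] = set()
    sub = tss[tss["chrom"] == chrom]
    for _, row in sub.iterrows():
        strand = row.get("strand", "+")
        if strand not in ("+", "-"):
            strand = "+"
        d = (row["pos"] - pos) if strand == "+" else (pos - row["pos"])
        if 0 <= d <= 200:
            out.add("TSS200")
        elif 200 < d <= 1500:
            out.add("TSS1500")
    if gene_model is not None and len(gene_model):
        sub = gene_model[
            (gene_model["chrom"] == chrom)
            & (gene_model["start"] <= pos)
            & (pos < gene_model["end"])
        ]
        out.update(sub["feature"].tolist())
    if not out:
        out.add("Intergenic")
    return out


def classify_cgi_context(midpoint: int, chrom: str, cgi: list[GenomicInterval]) -> str:
    """CGI-relative class of a position: island, shore (0-2 kb), shelf (2-4 kb), open sea.

    N (north) is the 5' side of the island on + orientation, i.e. lower
    coordinates; S the higher side. Classification uses the nearest island.
    """
    best: tuple[int, str] | None = None
    for iv in cgi:
        if iv.chrom != chrom:
            continue
        if iv.start <= midpoint < iv.end:
            return "Island"
        if midpoint < iv.start:
            dist, side = iv.start - midpoint, "N"
        else:
            dist, side = midpoint - (iv.end - 1), "S"
        if best is None or dist < best[0]:
            best = (dist, side)
    if best is None:
        return "OpenSea"
    dist, side = best
    if dist <= SHORE_BP:
        return f"{side}_Shore"
    if dist <= SHELF_BP:
        return f"{side}_Shelf"
    return "OpenSea"


def classify_block_context(
    block: GenomicBlock,
    annotation: pd.DataFrame,
    tss: pd.DataFrame,
    cgi: list[GenomicInterval],
    gene_model: pd.DataFrame | None = None,
) -> GenomicBlock:
    """Assign gene_context (union over member probes) and cgi_context (midpoint).

    ``tss`` needs columns chrom, pos and optionally strand/gene; ``gene_model``
    (optional) columns chrom, start, end, feature with feature in
    {UTR5, FirstExon, Body, UTR3}. Mutates and returns the block.
    """
    ann = annotation.set_index("probe_id")
    ctx: set[str] = set()
    for pid in block.probe_ids:
        row = ann.loc[pid]
        ctx |= _gene_context_for_position(row["chrom"], int(row["pos"]), tss, gene_model)
    block.gene_context = ctx
    block.cgi_context = classify_cgi_context(
        block.interval.midpoint, block.interval.chrom, cgi
    )
    return block


def blocks_to_frame(blocks: list[GenomicBlock]) -> pd.DataFrame:
    """Block definition table (block_id, chrom, start, end, n_probes, contexts)."""
    return pd.DataFrame(
        {
            "block_id": [b.block_id for b in blocks],
            "chrom": [b.interval.chrom for b in blocks],
            "start": [b.interval.start for b in blocks],
            "end": [b.interval.end for b in blocks],
            "n_probes": [b.n_probes for b in blocks],
            "probe_ids": [",".join(b.probe_ids) for b in blocks],
            "gene_context": [";".join(sorted(b.gene_context)) for b in blocks],
            "cgi_context": [b.cgi_context if b.cgi_context else "" for b in blocks],
        }
    )


def frame_to_blocks(frame: pd.DataFrame) -> list[GenomicBlock]:
    """Inverse of :func:`blocks_to_frame`."""
    out = []
    for _, row in frame.iterrows():
        gene_ctx = set(str(row.get("gene_context", "") or "").split(";")) - {""}
        out.append(
            GenomicBlock(
                block_id=row["block_id"],
                interval=GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
                probe_ids=str(row["probe_ids"]).split(","),
                gene_context=gene_ctx,
                cgi_context=(row.get("cgi_context") or None),
            )
        )
    return out
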