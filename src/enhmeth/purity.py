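"""Tumor cell content from methylation marker blocks.

Markers are blocks essentially unmethylated in every normal sample
(leukocytes and normal adipose tissue, β < 0.2) but methylated (β > 0.8)
in at least 3 of 4 tumor cell lines. Under a two-component mixture — tumor
cells fully methylated at markers, stromal cells unmethylated — the
observed marker β of a specimen is affine in its tumor fraction, so mean
marker β estimates purity directly; optional endpoint calibration rescales
it between the observed normal and cell-line extremes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import BetaMatrix, SampleMetadata
from .errors import InsufficientDataError

logger = logging.getLogger(__name__)

LOW_THR = 0.2    # unmethylated bound in normals
HIGH_THR = 0.8   # methylated bound in cell lines
MIN_LINES = 3    # "three or more of four" cell lines


@dataclass
class PurityEstimate:
    sample_id: str
    purity: float
    n_markers_used: int
    marker_beta_mean: float
    marker_beta_sd: float

    def __post_init__(self):
        assert 0.0 <= self.purity <= 1.0


def select_marker_blocks(
    block_matrix: BetaMatrix,
    normals: Sequence[str],
    cell_lines: Sequence[str],
    low_thr: float = LOW_THR,
    high_thr: float = HIGH_THR,
    min_lines: int = MIN_LINES,
) -> set[str]:
    """Blocks with β < ``low_thr`` in ALL normals and β > ``high_thr`` in
    at least ``min_lines`` cell lines.

    NA in a normal disqualifies a block (the all-normals condition cannot
    be verified); NA in a cell line simply does not count toward
    ``min_lines``. An empty result is a warning, not an error.
    """
    if len(normals) < 1:
        raise InsufficientDataError("marker selection needs >= 1 normal sample")
    if len(cell_lines) < min_lines:
        raise InsufficientDataError(
            f"marker selection needs >= {min_lines} cell lines, got {len(cell_lines)}"
        )
    vals = block_matrix.values
    norm = vals[list(normals)].to_numpy(dtype=float)
    cl = vals[list(cell_lines)].to_numpy(dtype=float)
    low_all = np.all(np.nan_to_num(norm, nan=np.inf) < low_thr, axis=1)
    high_n = np.nansum(cl > high_thr, axis=1)
    sel = low_all & (high_n >= min_lines)
    markers = set(np.asarray(block_matrix.row_ids)[sel])
    if not markers:
        logger.warning("no marker blocks satisfy the selection rule")
    return markers


def estimate_purity(
    block_matrix: BetaMatrix,
    markers: Iterable[str],
    sample: str,
    calibrate: bool = False,
    normals: Sequence[str] | None = None,
    cell_lines: Sequence[str] | None = None,
    min_markers: int = 10,
) -> PurityEstimate:
    """Purity of one sample as mean marker β, clipped to [0, 1].

    With ``calibrate=True`` the mean is affinely rescaled between the
    mean marker β of the normal samples (purity 0 endpoint) and of the
    cell lines (purity 1 endpoint).
    """
    marker_ids = [m for m in markers if m in set(block_matrix.row_ids)]
    col = block_matrix.values.loc[marker_ids, sample].to_numpy(dtype=float)
    col = col[np.isfinite(col)]
    if len(col) < min_markers:
        raise InsufficientDataError(
            f"sample {sample}: only {len(col)} usable markers (< {min_markers})"
        )
    mean = float(col.mean())
    purity = mean
    if calibrate:
        if not normals or not cell_lines:
            raise InsufficientDataError("calibration needs normals and cell_lines")
        b0 = float(np.nanmean(block_matrix.values.loc[marker_ids, list(normals)].to_numpy()))
        b1 = float(np.nanmean(block_matrix.values.loc[marker_ids, list(cell_lines)].to_numpy()))
        if b1 - b0 < 1e-6:
            raise InsufficientDataError("calibration endpoints coincide")
        purity = (mean - b0) / (b1 - b0)
    return PurityEstimate(
        sample_id=sample,
        purity=float(np.clip(purity, 0.0, 1.0)),
        n_markers_used=len(col),
        marker_beta_mean=mean,
        marker_beta_sd=float(col.std(ddof=1)) if len(col) > 1 else 0.0,
    )


def estimate_purities(
    block_matrix: BetaMatrix,
    metadata: SampleMetadata,
    markers: Iterable[str] | None = None,
    calibrate: bool = False,
) -> pd.DataFrame:
    """Marker selection plus purity for every tumor sample; returns a table."""
    normals = [
        s
        for g in ("normal_adipose", "leukocyte")
        for s in metadata.samples_in_group(g)
        if s in block_matrix.sample_ids
    ]
    cell_lines = [
        s for s in metadata.samples_in_group("cell_line") if s in block_matrix.sample_ids
    ]
    if markers is None:
        markers = select_marker_blocks(block_matrix, normals, cell_lines)
    tumors = [
        s
        for g in ("WDLPS", "DDLPS")
        for s in metadata.samples_in_group(g)
        if s in block_matrix.sample_ids
    ]
    rows = []
    for s in tumors:
        est = estimate_purity(
            block_matrix, markers, s,
            calibrate=calibrate, normals=normals, cell_lines=cell_lines,
        )
        rows.append(
            {
                "sample_id": est.sample_id,
                "purity": est.purity,
                "n_markers_used": est.n_markers_used,
                "marker_beta_mean": est.marker_beta_mean,
                "marker_beta_sd": est.marker_beta_sd,
            }
        )
    return pd.DataFrame(rows)
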