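"""Domain types and readers/writers for the tabular and interval formats
the pipeline touches.

Conventions
-----------
* All genomic coordinates are 0-based half-open internally; BED files are
  read and written without shifting, probe positions are taken as 0-based
  single-base intervals.
* Chromosome names are matched by literal string equality (no ``chr``
  aliasing).
* Matrices and metadata travel as tab-delimited UTF-8 text with a header
  row; missing β-values are encoded as the literal token ``NA``.
* Writers always emit LF line endings.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError

NA_TOKEN = "NA"

#: sample groups; the first three are the ordered trend groups
TREND_GROUPS = ("normal_adipose", "WDLPS", "DDLPS")
ALL_GROUPS = TREND_GROUPS + ("leukocyte", "cell_line")

GENE_CONTEXTS = ("TSS200", "TSS1500", "UTR5", "FirstExon", "Body", "UTR3", "Intergenic")
CGI_CONTEXTS = ("N_Shelf", "N_Shore", "Island", "S_Shore", "S_Shelf", "OpenSea")


class FeatureLevel(str, Enum):
    probe = "probe"
    block = "block"


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally named/scored/stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        if not self.chrom:
            raise FormatError("interval with empty chromosome name")
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class BetaMatrix:
    """Features × samples matrix of methylation β-values in [0, 1].

    ``values`` is a pandas DataFrame indexed by probe or block identifier
    with one column per sample. NaN marks missing values; every non-missing
    entry is validated to lie in [0, 1] at construction.
    """

    values: pd.DataFrame
    feature_level: FeatureLevel = FeatureLevel.probe

    def __post_init__(self):
        if isinstance(self.feature_level, str):
            self.feature_level = FeatureLevel(self.feature_level)
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()[:5]
            raise FormatError(f"duplicate feature ids: {dup}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].tolist()[:5]
            raise FormatError(f"duplicate sample ids: {dup}")
        arr = self.values.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1) | np.isinf(arr)
        if bad.any():
            rows = idx[np.where(bad.any(axis=1))[0]].tolist()[:5]
            raise FormatError(
                f"β-values outside [0, 1] in rows {rows} (first 5 shown)"
            )

    @property
    def row_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_rows(self, row_ids: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(row_ids)], self.feature_level)

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.values[list(sample_ids)], self.feature_level)


@dataclass
class SampleMetadata:
    """Per-sample group labels and trend ordering.

    ``table`` columns: ``sample_id``, ``group`` (one of :data:`ALL_GROUPS`),
    ``trend_rank`` (0/1/2 for normal_adipose < WDLPS < DDLPS, NA otherwise)
    and optional free-text ``site``.
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"sample_id", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"metadata missing columns {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id in metadata")
        bad = ~self.table["group"].isin(ALL_GROUPS)
        if bad.any():
            raise FormatError(
                f"unknown group labels: {sorted(self.table.loc[bad, 'group'].unique())}"
            )
        if "trend_rank" not in self.table.columns:
            ranks = {g: i for i, g in enumerate(TREND_GROUPS)}
            self.table = self.table.assign(
                trend_rank=self.table["group"].map(ranks)
            )
        self.table = self.table.set_index("sample_id", drop=False)

    def samples_in_group(self, group: str) -> list[str]:
        return self.table.loc[self.table["group"] == group, "sample_id"].tolist()

    def trend_groups(self) -> list[list[str]]:
        """Sample ids per trend group, ordered normal < WDLPS < DDLPS."""
        out = []
        for rank in (0, 1, 2):
            sel = self.table["trend_rank"] == rank
            out.append(self.table.loc[sel, "sample_id"].tolist())
        return out

    def validate_against(self, matrix: BetaMatrix) -> None:
        missing = set(matrix.sample_ids) - set(self.table["sample_id"])
        if missing:
            raise ConsistencyError(
                f"samples in matrix without metadata: {sorted(missing)}"
            )


#: columns of a probe annotation table
PROBE_ANNOTATION_COLUMNS = ("probe_id", "chrom", "pos", "design_type")


def validate_probe_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate a probe-annotation table (probe_id, chrom, pos, design_type[,…])."""
    missing = set(PROBE_ANNOTATION_COLUMNS) - set(annotation.columns)
    if missing:
        raise FormatError(f"annotation missing columns {sorted(missing)}")
    if annotation["probe_id"].duplicated().any():
        dup = annotation.loc[annotation["probe_id"].duplicated(), "probe_id"]
        raise FormatError(f"duplicate probe ids: {dup.tolist()[:5]}")
    bad = ~annotation["design_type"].isin(["I", "II"])
    if bad.any():
        raise FormatError(
            f"design_type must be 'I' or 'II'; offending probes: "
            f"{annotation.loc[bad, 'probe_id'].tolist()[:5]}"
        )
    if (annotation["pos"] < 0).any():
        raise FormatError("negative probe positions")
    return annotation


# ---------------------------------------------------------------------------
# TSV matrix / metadata / annotation I/O
# ---------------------------------------------------------------------------

def read_beta_matrix(
    path, metadata_path=None, feature_level: str | FeatureLevel = FeatureLevel.probe
) -> BetaMatrix | tuple[BetaMatrix, SampleMetadata]:
    """Read a features × samples β TSV, optionally with its sample metadata.

    The first column holds feature ids, the header row sample ids. Values
    outside [0, 1] raise :class:`FormatError` naming the offending row;
    matrix samples missing from the metadata raise :class:`ConsistencyError`.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False)
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric β value in {path}: {exc}") from exc
    matrix = BetaMatrix(df, FeatureLevel(feature_level))
    if metadata_path is None:
        return matrix
    meta = read_sample_metadata(metadata_path)
    meta.validate_against(matrix)
    return matrix, meta


def write_beta_matrix(matrix: BetaMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = matrix.feature_level.value + "_id"
    with open(path, "w", newline="\n") as fh:
        # default float formatting = shortest round-trip repr, so written
        # matrices read back bit-exact
        df.to_csv(fh, sep="\t", na_rep=NA_TOKEN, lineterminator="\n")


def read_sample_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
    df["sample_id"] = df["sample_id"].astype(str)
    if "trend_rank" in df.columns:
        df["trend_rank"] = pd.to_numeric(df["trend_rank"], errors="coerce")
    return SampleMetadata(df)


def write_sample_metadata(meta: SampleMetadata, path) -> None:
    with open(path, "w", newline="\n") as fh:
        meta.table.to_csv(fh, sep="\t", index=False, na_rep=NA_TOKEN, lineterminator="\n")


def read_probe_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
    df["probe_id"] = df["probe_id"].astype(str)
    df["pos"] = pd.to_numeric(df["pos"]).astype(int)
    return validate_probe_annotation(df)


def write_probe_annotation(annotation: pd.DataFrame, path) -> None:
    validate_probe_annotation(annotation)
    with open(path, "w", newline="\n") as fh:
        annotation.to_csv(fh, sep="\t", index=False, na_rep=NA_TOKEN, lineterminator="\n")


# ---------------------------------------------------------------------------
# BED / bedGraph I/O
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED4/BED6 or 4-column bedGraph into intervals.

    A numeric fourth column is interpreted as a bedGraph score; a
    non-numeric one as a BED name. Columns 5 and 6 of BED6 are score and
    strand. Lines starting with ``track``, ``browser`` or ``#`` are skipped.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name, score, strand = None, None, "."
            if len(fields) == 4:
                try:
                    score = float(fields[3])
                except ValueError:
                    name = fields[3]
            elif len(fields) >= 5:
                name = fields[3] if fields[3] != "." else None
                if fields[4] != ".":
                    try:
                        score = float(fields[4])
                    except ValueError as exc:
                        raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
                if len(fields) >= 6:
                    strand = fields[5]
            out.append(GenomicInterval(chrom, start, end, strand, name, score))
    return out


def _format_score(score: float) -> str:
    return f"{score:.10g}"


def write_bed(intervals: Iterable[GenomicInterval], path, style: str = "auto") -> None:
    """Write intervals as BED3, bedGraph (4-col score) or BED6.

    ``style='auto'`` picks the narrowest format that preserves every field
    present: BED3 if only coordinates, bedGraph if only a score, BED6
    otherwise.
    """
    intervals = list(intervals)
    if style == "auto":
        has_name = any(iv.name is not None for iv in intervals)
        has_strand = any(iv.strand != "." for iv in intervals)
        has_score = any(iv.score is not None for iv in intervals)
        if has_name or has_strand:
            style = "bed6"
        elif has_score:
            style = "bedgraph"
        else:
            style = "bed3"
    with open(path, "w", newline="\n") as fh:
        for iv in intervals:
            if style == "bed3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            elif style == "bedgraph":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                    f"{_format_score(iv.score if iv.score is not None else 0.0)}\n"
                )
            elif style == "bed6":
                name = iv.name if iv.name is not None else "."
                score = _format_score(iv.score) if iv.score is not None else "."
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )
            else:
                raise ValueError(f"unknown BED style {style!r}")


def intervals_to_frame(intervals: Sequence[GenomicInterval]) -> pd.DataFrame:
    """Tabular view of an interval list (chrom, start, end, strand, name, score)."""
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "strand": [iv.strand for iv in intervals],
            "name": [iv.name for iv in intervals],
            "score": [iv.score for iv in intervals],
        }
    )
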