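"""Stage-sequential pipeline orchestration.

Stages run in the fixed order normalize → blocks → purity → dmr →
enhancers → enrich → explore; every stage reads its inputs from files and
writes its outputs before the next starts, so stages are independently
re-runnable and the only inter-stage contract is the file set. A JSON run
manifest records parameters, input checksums, per-stage row counts and
output checksums; re-running a completed pipeline with unchanged inputs
is a no-op unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bmiq, enhancers, explore, purity, trend_dmr
from . import blocks as blocks_mod
from .core_io import (
    BetaMatrix,
    FeatureLevel,
    read_bed,
    read_beta_matrix,
    read_probe_annotation,
    read_sample_metadata,
    write_bed,
    write_beta_matrix,
)
from .errors import ConfigError, EnhmethError

logger = logging.getLogger(__name__)

STAGES = ("normalize", "blocks", "purity", "dmr", "enhancers", "enrich", "explore")


@dataclass
class PipelineConfig:
    """Paths, stage toggles and all stage parameters."""

    beta: str
    annotation: str
    metadata: str
    peaks: str
    tss: str
    out_dir: str = "results"
    cgi: str | None = None
    tf_sites: str | None = None
    control: str | None = None
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # stage parameters (defaults follow the published analysis settings)
    max_gap: int = 500
    low_thr: float = 0.2
    high_thr: float = 0.8
    min_lines: int = 3
    calibrate_purity: bool = False
    p_thr: float = 0.01
    delta_thr: float = 0.0
    tss_window: int = 2000
    link_distance: int = 50_000
    top_sd: int = 30_000
    cluster_metric: str = "euclidean"
    cluster_linkage: str = "ward"
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if not (0 < self.p_thr <= 1):
            raise ConfigError("p_thr must lie in (0, 1]")
        if self.max_gap < 0 or self.tss_window < 0 or self.link_distance < 0:
            raise ConfigError("distances must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"bad pipeline config: {exc}") from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    with open(path, "w", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=index, na_rep="NA",
                  lineterminator="\n", float_format="%.10g")


def _log(stage: str, **kv) -> None:
    ts = time.strftime("%Y-%m-%dT%H:%M:%S")
    msg = " ".join(f"{k}={v}" for k, v in kv.items())
    print(f"{ts} stage={stage} {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Execute the enabled stages in order; returns the run manifest.

    Any stage failure aborts with the stage name and cause; the failing
    stage's partially written outputs are renamed with a ``.partial``
    suffix. Identical config + inputs reproduce identical outputs; an
    unchanged completed run is skipped unless ``force``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"

    input_paths = {
        k: getattr(config, k)
        for k in ("beta", "annotation", "metadata", "peaks", "tss", "cgi",
                  "tf_sites", "control")
        if getattr(config, k)
    }
    input_checksums = {k: _sha256(Path(p)) for k, p in input_paths.items()}
    params = dataclasses.asdict(config)

    if manifest_path.exists() and not force:
        old = json.loads(manifest_path.read_text())
        outputs_intact = all(
            Path(p).exists() and _sha256(Path(p)) == c
            for p, c in old.get("output_checksums", {}).items()
        )
        if (
            old.get("input_checksums") == input_checksums
            and old.get("parameters") == params
            and outputs_intact
        ):
            _log("pipeline", status="unchanged", action="skip")
            return old

    manifest: dict = {
        "parameters": params,
        "input_checksums": input_checksums,
        "stages": [],
        "row_counts": {},
        "output_checksums": {},
    }

    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            manifest["stages"].append({"name": stage, "status": "skipped"})
            _log(stage, status="skipped")
            continue
        t0 = time.time()
        written: list[Path] = []
        try:
            counts = _STAGE_FUNCS[stage](config, out, state, written)
        except Exception as exc:
            for p in written:
                if p.exists():
                    p.rename(p.with_suffix(p.suffix + ".partial"))
            raise EnhmethError(f"stage {stage!r} failed: {exc}") from exc
        for p in written:
            manifest["output_checksums"][str(p)] = _sha256(p)
        manifest["row_counts"].update(counts)
        manifest["stages"].append(
            {"name": stage, "status": "completed", "seconds": round(time.time() - t0, 3)}
        )
        _log(stage, status="completed", seconds=round(time.time() - t0, 2),
             **{k: v for k, v in counts.items()})

    with open(manifest_path, "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# --------------------------------------------------------------------------
# stage implementations: each takes (config, out_dir, shared state, written)
# --------------------------------------------------------------------------

def _load_matrix(config: PipelineConfig, out: Path) -> BetaMatrix:
    normalized = out / "normalized.tsv"
    if normalized.exists():
        return read_beta_matrix(normalized)
    return read_beta_matrix(config.beta)


def _stage_normalize(config, out, state, written):
    matrix, meta = read_beta_matrix(config.beta, config.metadata)
    ann = read_probe_annotation(config.annotation)
    norm, fits = bmiq.normalize_matrix(matrix, ann, seed=config.seed)
    path = out / "normalized.tsv"
    written.append(path)
    write_beta_matrix(norm, path)
    fit_path = out / "bmiq_fits.tsv"
    written.append(fit_path)
    _write_tsv(fits, fit_path)
    return {"probes_normalized": norm.shape[0]}


def _stage_blocks(config, out, state, written):
    ann = read_probe_annotation(config.annotation)
    matrix = _load_matrix(config, out)
    block_list = blocks_mod.aggregate_blocks(ann, max_gap=config.max_gap)
    tss = read_bed(config.tss)
    tss_df = pd.DataFrame(
        {"chrom": [t.chrom for t in tss], "pos": [t.start for t in tss],
         "strand": [t.strand for t in tss]}
    )
    cgi = read_bed(config.cgi) if config.cgi else []
    for blk in block_list:
        blk.cgi_context = blocks_mod.classify_cgi_context(
            blk.interval.midpoint, blk.interval.chrom, cgi
        )
    block_frame = blocks_mod.blocks_to_frame(block_list)
    bmat = blocks_mod.block_beta(matrix, block_list)
    p1, p2 = out / "blocks.tsv", out / "block_beta.tsv"
    written.extend([p1, p2])
    _write_tsv(block_frame, p1)
    write_beta_matrix(bmat, p2)
    state["blocks"] = block_list
    return {"blocks": len(block_list)}


def _read_block_matrix(out: Path) -> BetaMatrix:
    return read_beta_matrix(out / "block_beta.tsv", feature_level=FeatureLevel.block)


def _stage_purity(config, out, state, written):
    bmat = _read_block_matrix(out)
    meta = read_sample_metadata(config.metadata)
    table = purity.estimate_purities(bmat, meta, calibrate=config.calibrate_purity)
    path = out / "purity.tsv"
    written.append(path)
    _write_tsv(table, path)
    return {"tumor_samples": len(table)}


def _stage_dmr(config, out, state, written):
    bmat = _read_block_matrix(out)
    meta = read_sample_metadata(config.metadata)
    res = trend_dmr.call_trend_dmrs(
        bmat, meta, p_thr=config.p_thr, delta_thr=config.delta_thr
    )
    path = out / "dmr.tsv"
    written.append(path)
    _write_tsv(res, path)
    blocks_frame = pd.read_csv(out / "blocks.tsv", sep="\t")
    cgi_of = dict(zip(blocks_frame["block_id"], blocks_frame["cgi_context"].fillna("")))
    universe = set(res["block_id"])
    counts = {}
    for direction in ("hyper", "hypo"):
        ids = set(res.loc[res["direction"] == direction, "block_id"])
        counts[f"{direction}_dmrs"] = len(ids)
        if ids and any(cgi_of.values()):
            enr = trend_dmr.context_enrichment(ids, universe, lambda b: cgi_of[b] or "none")
            ep = out / f"dmr_enrichment_cgi_{direction}.tsv"
            written.append(ep)
            _write_tsv(enr, ep)
    return counts


def _stage_enhancers(config, out, state, written):
    peak_ivs = read_bed(config.peaks)
    peaks = enhancers.peaks_from_intervals(peak_ivs)
    control = read_bed(config.control) if config.control else None
    peaks = enhancers.subtract_background(peaks, control)
    tss = read_bed(config.tss)
    peaks = enhancers.exclude_tss_proximal(peaks, tss, window=config.tss_window)
    calls = enhancers.call_super_enhancers(peaks)
    enhancers.associate_genes(calls, tss, max_dist=config.link_distance)
    frame = enhancers.calls_to_frame(calls)
    p1 = out / "enhancer_calls.tsv"
    written.append(p1)
    _write_tsv(frame, p1)
    for cls in ("typical", "super"):
        path = out / f"{cls}_enhancers.bed"
        written.append(path)
        write_bed([p.interval for p in getattr(calls, cls)], path, style="bed3")
    state["calls"] = calls
    return {
        "peaks_retained": len(calls.ranked_peaks),
        "super_enhancers": len(calls.super),
    }


def _stage_enrich(config, out, state, written):
    blocks_frame = pd.read_csv(out / "blocks.tsv", sep="\t")
    block_list = blocks_mod.frame_to_blocks(blocks_frame)
    dmr = pd.read_csv(out / "dmr.tsv", sep="\t")
    block_sets = {}
    for direction in ("hyper", "hypo"):
        ids = set(dmr.loc[dmr["direction"] == direction, "block_id"])
        if ids:
            block_sets[direction] = ids
    region_sets = {}
    for cls in ("typical", "super"):
        path = out / f"{cls}_enhancers.bed"
        if path.exists():
            region_sets[f"{cls}_enhancer"] = read_bed(path)
    if config.tf_sites:
        region_sets["tf_sites"] = read_bed(config.tf_sites)
    if not block_sets or not region_sets:
        logger.warning("nothing to enrich (no DMRs or no region sets)")
        return {"overlap_rows": 0}
    table = enhancers.overlap_fractions(block_sets, block_list, region_sets)
    path = out / "overlap.tsv"
    written.append(path)
    _write_tsv(table, path)
    return {"overlap_rows": len(table)}


def _stage_explore(config, out, state, written):
    bmat = _read_block_matrix(out)
    n = min(config.top_sd, bmat.shape[0])
    top = explore.select_top_sd(bmat, n)
    corr = explore.spearman_matrix(top)
    p1 = out / "spearman.tsv"
    written.append(p1)
    _write_tsv(corr, p1, index=True)
    pca_res = explore.pca(top.subset_rows(
        [r for r in top.row_ids if not top.values.loc[r].isna().any()]
    ))
    p2 = out / "pca_scores.tsv"
    written.append(p2)
    _write_tsv(pca_res.scores, p2, index=True)
    clust = explore.hierarchical_cluster(
        top, metric=config.cluster_metric, linkage=config.cluster_linkage
    )
    p3 = out / "dendrogram.nwk"
    written.append(p3)
    with open(p3, "w", newline="\n") as fh:
        fh.write(clust.newick + "\n")
    return {"top_sd_rows": n}


_STAGE_FUNCS = {
    "normalize": _stage_normalize,
    "blocks": _stage_blocks,
    "purity": _stage_purity,
    "dmr": _stage_dmr,
    "enhancers": _stage_enhancers,
    "enrich": _stage_enrich,
    "explore": _stage_explore,
}
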