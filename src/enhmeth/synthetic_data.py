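"""Synthetic cohort and enhancer-signal generator with known ground truth.

Emulates every input the pipeline consumes: a probe-level β matrix over
three ordered sample groups (normal adipose < WDLPS < DDLPS) plus normal
leukocytes and tumor cell lines; probe annotation with two design
chemistries and a stated compression of type II values toward 0.5; probe
coordinates laid out so block chaining at the 500 bp gap is exercised;
tumor samples mixed with a stromal profile at known purity; marker blocks
constructed to satisfy the purity-selection rule; and an H3K27ac-like
peak track whose ranked total-signal curve crosses slope 1 near the
planted super-enhancer fraction, with a subset of hypermethylated blocks
placed inside super-enhancers to create a detectable overlap enrichment.

Noise model: each probe's β in each sample is drawn from
Beta(μφ, (1-μ)φ) around the block mean μ with concentration φ
(default 30, per-probe SD ≈ 0.08 at μ = 0.5, comparable to array-like
dispersion). All randomness flows from one integer seed; identical
configs produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import blocks as blocks_mod
from .core_io import (
    BetaMatrix,
    FeatureLevel,
    GenomicInterval,
    SampleMetadata,
    write_bed,
    write_beta_matrix,
    write_probe_annotation,
    write_sample_metadata,
)
from .enhancers import SignalPeak
from .errors import ConfigError


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    # cohort layout
    n_blocks: int = 5000
    probes_per_block: int = 4
    n_chromosomes: int = 4
    # sample groups (trend cohort 6/6/9 plus leukocytes and cell lines)
    n_normal: int = 6
    n_wdlps: int = 6
    n_ddlps: int = 9
    n_leukocyte: int = 2
    n_cell_line: int = 4
    # planted signal
    n_hyper: int = 200
    n_hypo: int = 200
    n_marker: int = 262
    effect_means: tuple[float, float, float] = (0.2, 0.45, 0.7)
    precision: float = 30.0
    # purity markers: near-binary methylation states
    marker_tumor_mean: float = 0.95
    marker_stroma_mean: float = 0.03
    marker_precision: float = 100.0
    # tumor content of specimens (1.0 = pure tumor); per-sample overrides win
    purity_wdlps: float = 1.0
    purity_ddlps: float = 1.0
    purity_overrides: dict = field(default_factory=dict)
    # probe design bias
    type2_fraction: float = 0.5
    type2_bias: float = 0.3  # compression of type II values toward 0.5
    # enhancer signal
    enhancer_n_peaks: int = 10_000
    super_fraction: float = 0.05
    signal_noise_sd: float = 0.002  # small vs the tail's per-rank growth rate
    enhancer_hyper_fraction: float = 0.15  # hyper blocks planted inside supers
    enhancer_background_super: float = 0.02  # other blocks covered by supers
    enhancer_background_typical: float = 0.10
    n_tss: int = 300
    n_tf_sites: int = 400

    def validate(self) -> "SimulationConfig":
        counts = (
            self.n_blocks, self.probes_per_block, self.n_normal, self.n_wdlps,
            self.n_ddlps, self.n_leukocyte, self.n_cell_line, self.n_hyper,
            self.n_hypo, self.n_marker, self.enhancer_n_peaks, self.n_tss,
            self.n_tf_sites,
        )
        if any(c < 0 for c in counts):
            raise ConfigError("all counts must be >= 0")
        if self.n_hyper + self.n_hypo + self.n_marker > self.n_blocks:
            raise ConfigError("planted blocks exceed n_blocks")
        if not all(0 < m < 1 for m in self.effect_means):
            raise ConfigError("effect means must lie in (0, 1)")
        if self.precision <= 0 or self.marker_precision <= 0:
            raise ConfigError("precision must be positive")
        if not (0 < self.super_fraction < 1):
            raise ConfigError("super_fraction must lie in (0, 1)")
        if not (0 <= self.type2_bias < 1):
            raise ConfigError("type2_bias must lie in [0, 1)")
        for f in (self.purity_wdlps, self.purity_ddlps, *self.purity_overrides.values()):
            if not (0 <= f <= 1):
                raise ConfigError("purity fractions must lie in [0, 1]")
        return self


@dataclass
class GroundTruth:
    """Planted structure of one simulated bundle."""

    hyper_block_ids: list[str]
    hypo_block_ids: list[str]
    marker_block_ids: list[str]
    purity: dict  # tumor sample -> planted fraction
    super_peak_ids: list[str] = field(default_factory=list)
    planted_super_blocks: list[str] = field(default_factory=list)  # hyper in supers
    tf_hyper_blocks: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sample_ids(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for prefix, group, count, rank in (
        ("N", "normal_adipose", config.n_normal, 0),
        ("W", "WDLPS", config.n_wdlps, 1),
        ("D", "DDLPS", config.n_ddlps, 2),
        ("L", "leukocyte", config.n_leukocyte, None),
        ("C", "cell_line", config.n_cell_line, None),
    ):
        for i in range(count):
            rows.append(
                {
                    "sample_id": f"{prefix}{i + 1:02d}",
                    "group": group,
                    "trend_rank": rank,
                    "site": "",
                }
            )
    return pd.DataFrame(rows)


def _probe_layout(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Probe coordinates: intra-block gaps <= 500, inter-block gaps > 500.

    Every 50th block uses the boundary gaps (500 inside, 501 outside) so
    chaining at the threshold is exercised.
    """
    n_per_chrom = int(np.ceil(config.n_blocks / config.n_chromosomes))
    rows = []
    probe_counter = 0
    block_counter = 0
    for c in range(config.n_chromosomes):
        pos = int(rng.integers(1000, 5000))
        for _ in range(n_per_chrom):
            if block_counter >= config.n_blocks:
                break
            boundary = block_counter % 50 == 49
            for p in range(config.probes_per_block):
                probe_counter += 1
                rows.append(
                    {
                        "probe_id": f"cg{probe_counter:08d}",
                        "chrom": f"chr{c + 1}",
                        "pos": pos,
                        "design_type": "",
                        "sim_block": block_counter,
                    }
                )
                if p < config.probes_per_block - 1:
                    gap = 500 if boundary else int(rng.integers(20, 501))
                    pos += gap
            pos += 501 if boundary else int(rng.integers(501, 2001))
            block_counter += 1
    ann = pd.DataFrame(rows)
    design = np.where(
        rng.random(len(ann)) < config.type2_fraction, "II", "I"
    )
    ann["design_type"] = design
    return ann


def _draw_beta(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    mu = np.clip(mu, 1e-4, 1 - 1e-4)
    return rng.beta(mu * phi, (1 - mu) * phi)


def simulate_methylation_cohort(
    config: SimulationConfig,
) -> tuple[BetaMatrix, pd.DataFrame, SampleMetadata, GroundTruth, list]:
    """Generate (probe matrix, annotation, metadata, ground truth, blocks).

    Block roles (hyper / hypo / marker / null) are assigned by a seeded
    permutation over the chained-block partition of the generated probe
    layout, so ground-truth ids are exactly the ids the pipeline's own
    aggregation produces. Marker blocks are redrawn until the emitted
    (bias-included) block means satisfy the purity-selection rule, which
    keeps ground truth re-derivable from the emitted matrix.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta_table = _sample_ids(config)
    metadata = SampleMetadata(meta_table.copy())
    samples = meta_table["sample_id"].tolist()
    n_samples = len(samples)

    ann = _probe_layout(config, rng)
    block_list = blocks_mod.aggregate_blocks(
        ann[["probe_id", "chrom", "pos", "design_type"]], max_gap=500
    )
    assert len(block_list) == config.n_blocks, "layout must chain into n_blocks"
    n_blocks = config.n_blocks

    perm = rng.permutation(n_blocks)
    hyper_idx = perm[: config.n_hyper]
    hypo_idx = perm[config.n_hyper : config.n_hyper + config.n_hypo]
    marker_idx = perm[
        config.n_hyper + config.n_hypo : config.n_hyper + config.n_hypo + config.n_marker
    ]
    role = np.full(n_blocks, "null", dtype=object)
    role[hyper_idx] = "hyper"
    role[hypo_idx] = "hypo"
    role[marker_idx] = "marker"

    # per-sample purity
    purity = {}
    for _, row in meta_table.iterrows():
        s, g = row["sample_id"], row["group"]
        if g == "WDLPS":
            purity[s] = float(config.purity_overrides.get(s, config.purity_wdlps))
        elif g == "DDLPS":
            purity[s] = float(config.purity_overrides.get(s, config.purity_ddlps))

    group = meta_table["group"].to_numpy()
    f = np.array([purity.get(s, 1.0) for s in samples])  # 1.0 for non-tumor

    # block x sample mean matrix
    m0, m1, m2 = config.effect_means
    null_mu = rng.uniform(0.05, 0.95, size=n_blocks)
    tumor_mu = np.tile(null_mu[:, None], (1, n_samples))
    stroma_mu = np.tile(null_mu[:, None], (1, n_samples))
    is_w = group == "WDLPS"
    is_d = group == "DDLPS"
    is_cl = group == "cell_line"
    for idx, means in ((hyper_idx, (m0, m1, m2)), (hypo_idx, (m2, m1, m0))):
        a0, a1, a2 = means
        tumor_mu[idx, :] = a0
        tumor_mu[np.ix_(idx, np.where(is_w)[0])] = a1
        tumor_mu[np.ix_(idx, np.where(is_d | is_cl)[0])] = a2
        stroma_mu[idx, :] = a0
    tumor_mu[marker_idx, :] = config.marker_stroma_mean
    tumor_mu[np.ix_(marker_idx, np.where(is_w | is_d | is_cl)[0])] = config.marker_tumor_mean
    stroma_mu[marker_idx, :] = config.marker_stroma_mean

    mu = f[None, :] * tumor_mu + (1 - f[None, :]) * stroma_mu

    phi = np.full((n_blocks, 1), config.precision)
    phi[marker_idx] = config.marker_precision
    ppb = config.probes_per_block
    mu_probe = np.repeat(mu, ppb, axis=0)
    phi_probe = np.repeat(np.broadcast_to(phi, (n_blocks, n_samples)), ppb, axis=0)
    values = _draw_beta(rng, mu_probe, phi_probe)

    is2 = (ann["design_type"] == "II").to_numpy()
    values[is2] = 0.5 + (values[is2] - 0.5) * (1 - config.type2_bias)

    # enforce the marker rule on emitted block means (redraw failing markers)
    normal_cols = np.where((group == "normal_adipose") | (group == "leukocyte"))[0]
    cl_cols = np.where(is_cl)[0]
    for bi in marker_idx:
        rows = slice(bi * ppb, (bi + 1) * ppb)
        for _ in range(100):
            bm = values[rows].mean(axis=0)
            ok = np.all(bm[normal_cols] < 0.2) and np.sum(bm[cl_cols] > 0.8) >= min(
                3, len(cl_cols)
            )
            if ok:
                break
            redraw = _draw_beta(
                rng,
                mu_probe[rows],
                np.full((ppb, n_samples), config.marker_precision),
            )
            r2 = is2[rows]
            redraw[r2] = 0.5 + (redraw[r2] - 0.5) * (1 - config.type2_bias)
            values[rows] = redraw

    matrix = BetaMatrix(
        pd.DataFrame(values, index=ann["probe_id"].tolist(), columns=samples),
        FeatureLevel.probe,
    )
    block_ids = np.array([b.block_id for b in block_list])
    truth = GroundTruth(
        hyper_block_ids=sorted(block_ids[hyper_idx]),
        hypo_block_ids=sorted(block_ids[hypo_idx]),
        marker_block_ids=sorted(block_ids[marker_idx]),
        purity=purity,
    )
    annotation = ann[["probe_id", "chrom", "pos", "design_type"]].copy()
    return matrix, annotation, metadata, truth, block_list


def _tail_growth_rate(n_peaks: int, n_super: int) -> float:
    """Exponential growth per rank making the slope-1 crossing land about
    ``n_super`` ranks below the top (two fixed-point refinements)."""
    gamma = 4.6 / n_super
    for _ in range(2):
        gamma = np.log(max(n_peaks * gamma, 2.0)) / n_super
    return gamma


def simulate_enhancer_signal(
    config: SimulationConfig,
    block_list: list | None = None,
    truth: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[SignalPeak], list[GenomicInterval], list[GenomicInterval], GroundTruth]:
    """Generate (peaks, tss_track, tf_track, updated ground truth).

    Total signal follows a flat bulk plus an exponentially growing top
    tail covering ``super_fraction`` of peaks, so the rescaled rank curve
    crosses slope 1 near 1 - super_fraction. When cohort blocks and truth
    are supplied, a fraction of hyper blocks is covered by super peaks
    (and random blocks by background peaks) to create detectable overlap
    enrichment; TSS rows are placed to exercise the ±2 kb exclusion and
    the 50 kb gene linking.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if truth is None:
        truth = GroundTruth([], [], [], {})

    n = config.enhancer_n_peaks
    n_super = max(1, round(n * config.super_fraction))
    n_bulk = n - n_super
    bulk = rng.uniform(0.5, 1.5, size=n_bulk)
    gamma = _tail_growth_rate(n, n_super)
    tail = 1.5 * np.exp(gamma * np.arange(1, n_super + 1))
    tail *= np.exp(rng.normal(0, config.signal_noise_sd, size=n_super))
    signals = np.concatenate([bulk, tail])  # index >= n_bulk -> true super

    blocks_by_id = {b.block_id: b for b in (block_list or [])}
    hyper_ids = list(truth.hyper_block_ids)
    planted_blocks: list[str] = []
    peak_intervals: list[GenomicInterval | None] = [None] * n

    if block_list:
        n_plant = round(config.enhancer_hyper_fraction * len(hyper_ids))
        chosen = sorted(rng.choice(hyper_ids, size=n_plant, replace=False))
        planted_blocks = list(chosen)
        # planted supers take the strongest tail ranks so they survive the
        # discrete slope cutoff
        strong = np.arange(n - 1, n_bulk - 1, -1)
        plant_slots = strong[: len(chosen)]
        for slot, bid in zip(plant_slots, chosen):
            blk = blocks_by_id[bid].interval
            pad = int(rng.integers(200, 600))
            peak_intervals[slot] = GenomicInterval(
                blk.chrom, max(0, blk.start - pad), blk.end + pad
            )
        # background coverage: random blocks under remaining supers/typicals
        other_ids = [b.block_id for b in block_list if b.block_id not in set(chosen)]
        n_bg_super = min(
            round(config.enhancer_background_super * len(block_list)),
            n_super - len(chosen),
        )
        n_bg_typ = round(config.enhancer_background_typical * len(block_list))
        bg = rng.choice(other_ids, size=n_bg_super + n_bg_typ, replace=False)
        free_super = [i for i in range(n_bulk, n) if peak_intervals[i] is None]
        slots = list(rng.choice(free_super, size=n_bg_super, replace=False)) + list(
            rng.choice(n_bulk, size=n_bg_typ, replace=False)
        )
        for slot, bid in zip(slots, bg):
            blk = blocks_by_id[bid].interval
            pad = int(rng.integers(200, 600))
            peak_intervals[slot] = GenomicInterval(
                blk.chrom, max(0, blk.start - pad), blk.end + pad
            )

    # remaining peaks laid out beyond the block span on each chromosome
    chroms = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
    offsets = {c: 0 for c in chroms}
    for b in blocks_by_id.values():
        offsets[b.interval.chrom] = max(offsets[b.interval.chrom], b.interval.end)
    cursors = {c: offsets[c] + 10_000 for c in chroms}
    for i in range(n):
        if peak_intervals[i] is not None:
            continue
        c = chroms[i % len(chroms)]
        start = cursors[c] + int(rng.integers(500, 3000))
        length = int(rng.integers(600, 2000))
        peak_intervals[i] = GenomicInterval(c, start, start + length)
        cursors[c] = start + length

    peaks = [
        SignalPeak(iv, float(signals[i]) / len(iv))
        for i, iv in enumerate(peak_intervals)
    ]

    # TSS track: a slice adjacent to bulk background peaks (exercises the
    # ±2 kb exclusion), the rest scattered at linkable / non-linkable range
    tss: list[GenomicInterval] = []
    n_near = max(1, config.n_tss // 10)
    near_slots = rng.choice(n_bulk, size=n_near, replace=False)
    gi = 0
    for slot in near_slots:
        iv = peak_intervals[slot]
        gi += 1
        pos = iv.end + int(rng.integers(0, 1500))
        tss.append(GenomicInterval(iv.chrom, pos, pos + 1, "+", f"GENE{gi:04d}"))
    while gi < config.n_tss:
        gi += 1
        slot = int(rng.integers(0, n))
        iv = peak_intervals[slot]
        offset = int(rng.integers(5_000, 80_000))
        strand = "+" if rng.random() < 0.5 else "-"
        tss.append(
            GenomicInterval(iv.chrom, iv.end + offset, iv.end + offset + 1, strand, f"GENE{gi:04d}")
        )

    # TF binding sites: inside a subset of planted hyper blocks + background
    tf: list[GenomicInterval] = []
    tf_hyper: list[str] = []
    if hyper_ids and blocks_by_id:
        n_tf_hyper = min(len(hyper_ids) // 2, config.n_tf_sites)
        for bid in sorted(rng.choice(hyper_ids, size=n_tf_hyper, replace=False)):
            blk = blocks_by_id[bid].interval
            mid = blk.midpoint
            tf.append(GenomicInterval(blk.chrom, max(0, mid - 100), mid + 100))
            tf_hyper.append(bid)
    while len(tf) < config.n_tf_sites:
        c = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, cursors[c]))
        tf.append(GenomicInterval(c, start, start + 200))

    truth.super_peak_ids = [f"PK{i + 1:05d}" for i in range(n_bulk, n)]
    truth.planted_super_blocks = planted_blocks
    truth.tf_hyper_blocks = tf_hyper
    return peaks, tss, tf, truth


def simulate_bundle(config: SimulationConfig, out_dir) -> dict:
    """Run both generators and write the full input bundle to ``out_dir``.

    Returns a manifest of written paths. Files: beta.tsv, annotation.tsv,
    metadata.tsv, peaks.bedgraph, tss.bed, cgi.bed, tf_sites.bed,
    ground_truth.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, annotation, metadata, truth, block_list = simulate_methylation_cohort(config)
    peaks, tss, tf, truth = simulate_enhancer_signal(config, block_list, truth)

    # CpG-island track covering ~10% of blocks (midpoint inside the island)
    cgi_rng = np.random.default_rng(config.seed + 2)
    cgi_blocks = cgi_rng.choice(block_list, size=max(1, len(block_list) // 10), replace=False)
    cgi = sorted(
        (
            GenomicInterval(
                b.interval.chrom,
                max(0, b.interval.start - 100),
                b.interval.end + 100,
            )
            for b in cgi_blocks
        ),
        key=lambda iv: (iv.chrom, iv.start),
    )

    paths = {
        "beta": out / "beta.tsv",
        "annotation": out / "annotation.tsv",
        "metadata": out / "metadata.tsv",
        "peaks": out / "peaks.bedgraph",
        "tss": out / "tss.bed",
        "cgi": out / "cgi.bed",
        "tf_sites": out / "tf_sites.bed",
        "ground_truth": out / "ground_truth.json",
    }
    write_beta_matrix(matrix, paths["beta"])
    write_probe_annotation(annotation, paths["annotation"])
    write_sample_metadata(metadata, paths["metadata"])
    write_bed(
        [
            GenomicInterval(p.interval.chrom, p.interval.start, p.interval.end,
                            score=p.density)
            for p in peaks
        ],
        paths["peaks"],
        style="bedgraph",
    )
    write_bed(tss, paths["tss"], style="bed6")
    write_bed(cgi, paths["cgi"], style="bed3")
    write_bed(tf, paths["tf_sites"], style="bed3")
    truth.to_json(paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}
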