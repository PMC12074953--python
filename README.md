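# enhmeth

DNA-methylation analysis of enhancer dysregulation in cohorts with
ordered disease groups, built for the question of how dedifferentiated
liposarcoma (DDLPS) loses the adipogenic program: which genomic regions
gain methylation along normal adipose tissue → well-differentiated
liposarcoma (WDLPS) → DDLPS, and whether those regions concentrate in
adipocyte enhancers — especially super-enhancers — and transcription
factor binding sites.

The package is a library first (with an `examples/` directory of short
narrative scripts) plus a thin `enhmeth` command-line wrapper, and
covers the full desk-side pipeline:

* **core_io** — β-value matrices (TSV), sample metadata, probe
  annotation, BED/bedGraph intervals; rejecting validation, 0-based
  half-open coordinates.
* **bmiq** — beta-mixture quantile (BMIQ) normalization of type II
  probe bias: a 3-state beta mixture per probe type fitted by
  generalized EM, then the monotone quantile map of type II onto type I.
* **blocks** — chaining of probes within 500 bp into genomic blocks
  (GBs), block-level β, TSS- and CGI-relative context classes.
* **purity** — tumor cell content from marker blocks that are
  unmethylated (β < 0.2) in all normals and methylated (β > 0.8) in ≥ 3
  of 4 cell lines; purity = mean marker β, optionally
  endpoint-calibrated.
* **trend_dmr** — Jonckheere–Terpstra ordered-trend test per block,

      U = Σ_{i<j} [ #{y > x} + ½·#{y = x} ],  (x, y) ∈ gᵢ × gⱼ, i < j,

  with tie-corrected null variance and a refined (Edgeworth-corrected)
  normal p-value; hyper/hypo DMR calls at P < 0.01 by the sign of Δβ =
  mean β(DDLPS) − mean β(normal); hypergeometric context enrichment.
* **enhancers** — super-enhancer classification from ranked
  background-subtracted H3K27ac signal (rpm/bp × length): rescale rank
  and signal to [0, 1], cut where the curve's slope exceeds and stays
  above 1; ±2 kb TSS exclusion; 50 kb gene linking; block-set overlap
  fractions with enrichment tests.
* **explore** — top-SD feature selection, Spearman correlation, PCA,
  hierarchical clustering (Newick output).
* **synthetic_data** — a seeded generator for every pipeline input with
  known ground truth (planted trend blocks, purity mixtures, marker
  blocks, heavy-tailed enhancer signal with a known super fraction).
* **pipeline / cli** — stage-sequential orchestration with a JSON run
  manifest, idempotent reruns, and `enhmeth
  simulate|normalize|blocks|purity|dmr|enhancers|enrich|explore|run`.

## Worked example

```python
from enhmeth import (SimulationConfig, simulate_methylation_cohort,
                     block_beta, call_trend_dmrs)

config = SimulationConfig(seed=2, n_blocks=2000, n_hyper=100, n_hypo=100,
                          n_marker=0, type2_bias=0.0)
matrix, annotation, metadata, truth, blocks = simulate_methylation_cohort(config)
results = call_trend_dmrs(block_beta(matrix, blocks), metadata, p_thr=0.01)
print(results["direction"].value_counts())
```

Running `python examples/04_trend_dmrs.py` (the same computation)
prints:

```
blocks tested        : 2000
called hyper / hypo  : 105 / 105
planted hyper found  : 100 of 100
planted hypo found   : 100 of 100
```

All 100 planted rising-trend blocks are recovered as hypermethylated
and all 100 falling ones as hypomethylated, with 10 additional null
blocks called across both directions — consistent with the ~1% false
positive rate expected when thresholding raw P at 0.01 over 1,800 null
blocks. The other scripts in `examples/` demonstrate BMIQ
normalization, block aggregation and context classes, purity recovery
from planted mixtures, super-enhancer calling, and the full seven-stage
pipeline with its overlap-enrichment readout.

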