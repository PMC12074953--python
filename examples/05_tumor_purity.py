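"""Estimate tumor cell content from methylation marker blocks.

Markers are unmethylated (β < 0.2) in every normal sample but methylated
(β > 0.8) in at least 3 of 4 tumor cell lines; the mean marker β of a
specimen is then affine in its tumor fraction.
"""

from enhmeth import SimulationConfig, block_beta, estimate_purity, select_marker_blocks
from enhmeth.synthetic_data import simulate_methylation_cohort

true_fractions = {"D01": 0.3, "D02": 0.6, "D03": 0.9}
config = SimulationConfig(seed=3, n_blocks=1000, n_hyper=0, n_hypo=0,
                          n_marker=120, purity_overrides=true_fractions,
                          type2_bias=0.0)
matrix, annotation, metadata, truth, blocks = simulate_methylation_cohort(config)
bm = block_beta(matrix, blocks)

normals = metadata.samples_in_group("normal_adipose") + metadata.samples_in_group("leukocyte")
lines = metadata.samples_in_group("cell_line")
markers = select_marker_blocks(bm, normals, lines)
print(f"marker blocks selected: {len(markers)} (planted: {len(truth.marker_block_ids)})")

print(f"{'sample':8s} {'true f':>7s} {'estimate':>9s}")
for sample, f in true_fractions.items():
    est = estimate_purity(bm, markers, sample, calibrate=True,
                          normals=normals, cell_lines=lines)
    print(f"{sample:8s} {f:7.2f} {est.purity:9.3f}")
# Calibration rescales the mean marker β between the normal (purity 0)
# and cell-line (purity 1) endpoints, so estimates track the planted
# tumor fractions.
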