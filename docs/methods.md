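# Methods

`enhmeth` implements a DNA-methylation analysis pipeline for cohorts with
ordered disease groups — here normal adipose tissue < well-differentiated
liposarcoma (WDLPS) < dedifferentiated liposarcoma (DDLPS) — that links
hypermethylated regions to adipocyte enhancer classes. This note records
the models, the parameters that matter, the numerical choices, and what
the bundled synthetic data does and does not establish.

## Data model

Methylation is carried as β-values in [0, 1] (0 unmethylated, 1 fully
methylated), probes × samples, with missing values as explicit NA and
pairwise exclusion in every statistic. Genomic coordinates are 0-based
half-open everywhere; chromosome names match by literal string equality.
Validation is rejecting: no downstream operation ever sees a β outside
[0, 1].

## Probe-to-block aggregation

Array probes are chained into genomic blocks by single-linkage: a probe
joins the current block when its distance to the previous probe on the
chromosome is ≤ `max_gap` (default 500 bp). Chaining rather than fixed
windows was chosen because it is deterministic, anchor-free, and matches
the intuition that "probes within 500 bp" describes inter-probe
proximity; a gap of exactly 500 bp chains, 501 bp splits. Block β is the
arithmetic mean over member probes (NA-excluded); the aggregator is a
design choice, as is reporting a block's gene context as the union of
member-probe categories (TSS200 = 0–200 bp upstream, TSS1500 =
200–1,500 bp upstream, then 5'UTR / first exon / body / 3'UTR from a
feature model, intergenic as fallback). CGI context uses the block
midpoint: island if inside; shore within 0–2 kb of the nearest island
edge; shelf within 2–4 kb; open sea beyond; N is the lower-coordinate
side. The 2/4 kb shore/shelf distances follow the platform's standard
convention.

## BMIQ normalization

Type II Infinium probes report β compressed toward 0.5 relative to
type I. Beta-mixture quantile normalization fits a three-state beta
mixture (unmethylated U, hemimethylated H, methylated M) to each probe
type within a sample and maps type II onto type I:

* U-state values (maximum posterior responsibility; ties resolved toward
  the lower-mean state) are transformed through the component quantile
  map F₁⁻¹(F₂(x)) of the U components, M-state values through the
  corresponding survival-function map.
* H-state values are linearly dilated from the interval between the
  empirical state boundaries (largest U-assigned input, smallest
  M-assigned input) onto the images of those boundaries. Empirical
  extremes were preferred over posterior-0.5 component quantiles because
  they make the transform exactly the identity when the two fits
  coincide.
* A final isotonic pass (running maximum over the sorted inputs)
  guarantees the transform never inverts the order of two inputs, so
  within-sample probe ranking is preserved by construction.

The mixture is fitted by generalized EM: the E-step is exact; the M-step
maximizes each component's weighted beta log-likelihood with L-BFGS-B on
log-shape parameters (analytic gradient) and keeps the previous
parameters whenever the optimizer fails to improve, so the observed-data
log-likelihood is non-decreasing at every iteration. Initialization
splits the data at the 1/3 and 2/3 empirical quantiles with
method-of-moments shapes per slice; it is deterministic, and the `seed`
argument exists only for interface stability. Convergence is declared
when the mean log-likelihood gain per observation drops below `tol`
(default 1e-5); a per-observation criterion keeps the stopping rule
invariant to sample size, which matters because genome-wide β
distributions are not literally three-component mixtures and absolute
increments plateau without shrinking to zero. Values are clipped to
[1e-6, 1−1e-6]; constant input raises a degenerate-input error; at least
50·k values are required. Normalization is applied per sample (whether
pooling would be preferable is an open question of the underlying
protocol; per-sample is the common choice and ours).

One practical consequence, visible in the end-to-end synthetic run: when
the planted type II bias is identical across samples, per-sample
normalization introduces small sample-specific monotone distortions
(each sample's mixture fit differs by sampling noise), which inflates
the trend-significant count above the planted number. This is a property
of per-sample normalization on non-mixture-shaped data, not of the test.

## Tumor purity from marker blocks

Marker blocks are unmethylated (β < 0.2) in every normal sample
(normal adipose and leukocytes) and methylated (β > 0.8) in at least 3
of 4 tumor cell lines. Under a two-component tissue model — tumor cells
fully methylated at markers, stroma unmethylated — observed marker β is
affine in tumor fraction, so purity is estimated as the mean marker β,
clipped to [0, 1]; the mean is the simplest estimator consistent with
the marker definition. Optional calibration rescales the mean between
the observed normal-sample endpoint (purity 0) and cell-line endpoint
(purity 1). At least 10 non-missing markers are required per sample.

## Ordered-trend DMR calling

The Jonckheere–Terpstra statistic for k ordered groups is

U = Σ_{i<j} [ #{(x,y) ∈ gᵢ×gⱼ : y > x} + ½·#{y = x} ],

with null mean (N² − Σnᵢ²)/4 and the standard tie-corrected null
variance built from group sizes and pooled tie multiplicities. The
default p-value is a refined normal approximation: continuity-corrected
(±0.5) normal with an Edgeworth fourth-cumulant term,

P(U ≤ u) ≈ Φ(z) − (γ₂/24)(z³ − 3z)φ(z),

where the excess kurtosis γ₂ of the tie-free null is computed exactly
from the classical decomposition of U into independent Mann–Whitney
components (group j versus the pooled earlier groups), whose pmfs are
obtained by dynamic programming and cached per group-size tuple. The
term is skipped when ties are present. The refinement matters at small
groups: at sizes (3,3,3) the plain corrected normal deviates from
exhaustive enumeration by up to 0.014, the refined version by ≤ 0.003.
Exact enumeration (bounded at 10⁶ arrangements) and permutation methods
are available for verification. Two-sided p = 2·min(P(≥U), P(≤U)),
capped at 1; zero null variance yields z = 0, p = 1.

A block is hypermethylated when p < 0.01 and Δβ (mean of the last group
minus mean of the first) exceeds `delta_thr`, hypomethylated when it
falls below −`delta_thr`. `delta_thr` defaults to 0 — direction by sign
alone — because the published analysis thresholds raw P at 0.01 without
a stated effect cutoff; a Δβ filter is exposed as a flag since one is
plausible. No multiple-testing correction gates the calls; a
Benjamini–Hochberg column is emitted for information. Blocks with fewer
than two non-missing values in any group get p = NA and direction
`none`.

Category enrichment of a DMR set against the block universe uses the
two-sided Fisher exact test (hypergeometric point-mass summation) per
label. Being an exact conditional test its null p-values are discrete
and super-uniform (conservative), never anti-conservative; tests assert
exactly that.

## Super-enhancer classification

Peaks carry read density in rpm/bp; background subtraction removes the
base-weighted mean control density over each peak, floored at 0. Peaks
intersecting ±2,000 bp around any TSS are excluded. The remaining peaks
are ranked ascending by total signal (density × length — "total" signal;
ranking by raw density is available as a flag), rank and signal are each
min-max rescaled to [0, 1], and the slope at every interior point is
taken by central finite difference. The cutoff is the first interior
index from which the slope exceeds 1 and stays above 1 to the end of the
curve (a monotone-tail criterion that makes the discretization
deterministic and robust to isolated slope spikes in the bulk); peaks
strictly above it are super-enhancers. The inequality is strict, so an
exactly linear or constant curve yields none. No peak stitching is
performed (a stitching distance flag exists but defaults off). Genes are
linked to an enhancer when the TSS lies within 50 kb of the nearer
enhancer edge (0 inside).

Overlap statistics count a block as hitting a region set when its
interval intersects at least one region; each named block set is
compared to the full block universe with the same two-sided
hypergeometric test as context enrichment.

## Exploratory views

Top-variance selection ranks rows by NA-excluded sample standard
deviation (n−1 denominator), ties broken lexicographically by row id.
Spearman correlation is pairwise-complete with midrank ties (NA when
fewer than 3 shared rows). PCA centers features without scaling (β is
already bounded and on one scale) and treats samples as observations;
components come from the SVD of the centered matrix. Hierarchical
clustering defaults to Euclidean distance with Ward linkage — the
underlying study names its software but not its metric/linkage, and
Ward/Euclidean recovers planted group structure most stably in our
simulations; both are flags. Feature rows containing any NA are dropped
before distances are computed. Dendrograms are also serialized as
Newick with branch lengths from merge heights.

## Synthetic data generator

The generator emulates the full input bundle under known ground truth.
Defaults are the documented study conditions:

| parameter | default | meaning |
| --- | --- | --- |
| group sizes | 6 / 6 / 9 (+2 leukocytes, +4 cell lines) | trend cohort |
| n_blocks × probes | 5,000 × 4 | genomic blocks |
| planted hyper/hypo | 200 / 200 | monotone-trend blocks |
| effect means | 0.2 / 0.45 / 0.7 | group means of planted blocks |
| precision φ | 30 | Beta(μφ, (1−μ)φ) noise; SD ≈ 0.08 at μ = 0.5 |
| marker blocks | 262 | purity markers (means 0.03 / 0.95, φ = 100) |
| tumor purity | 1.0 | per-sample overrides for mixture studies |
| type2_bias | 0.3 | compression of type II values toward 0.5 |
| peaks / super fraction | 10,000 / 0.05 | enhancer signal |

Null blocks share one μ ~ Uniform(0.05, 0.95) across groups; planted
blocks use the ordered mean vector (reversed for hypo); tumor samples
observe μ = f·μ_tumor + (1−f)·μ_stroma with the stromal profile fixed to
the normal-group mean (0.03 at markers), so purity mixtures are linear
in f. Marker blocks are redrawn (seeded, bounded retries) until the
emitted block means satisfy the selection rule, keeping ground truth
exactly re-derivable from the emitted matrix. Probe layout draws
intra-block gaps in [20, 500] and inter-block gaps in [501, 2000], with
every 50th block placed at the 500/501 boundary so chaining is exercised
at the threshold; block roles are assigned over the chained partition
itself, so ground-truth ids equal pipeline ids.

Enhancer total signal is a flat bulk (Uniform(0.5, 1.5)) plus an
exponentially growing top tail covering `super_fraction` of peaks; the
growth rate per rank is set by a two-step fixed point of
γ = ln(nγ)/n_super so the rescaled curve crosses slope 1 about n_super
ranks below the top. Tail jitter (lognormal, σ = 0.002) is kept well
below the per-rank growth so the discrete slope run stays monotone near
the crossing; with larger jitter the monotone-tail cutoff drifts deep
into the tail. A configurable fraction of hyper blocks (default 0.15) is
covered by super peaks — assigned the strongest tail ranks so they
survive the discrete cutoff — and random blocks are covered by further
super and typical peaks to give the universe a realistic baseline
overlap. TSS rows are planted both adjacent to bulk peaks (exercising
the ±2 kb exclusion) and at 5–80 kb offsets (exercising the 50 kb
linking); TF sites cover half the hyper blocks plus background.

All randomness flows from one integer seed through a single
`numpy.random.Generator`; identical configs write byte-identical files
(fixed float formatting, LF endings).

What passing on this generator does not show: the simulator has no
chromosome-scale CpG density structure, no realistic probe manifest, no
intertumoral heterogeneity among DDLPS samples (pairwise DDLPS
correlations come out near 0.98, unlike a heterogeneous real cohort),
sample-invariant type II bias, and a stylized enhancer signal law.
Results on real arrays additionally depend on upstream steps this
package deliberately excludes (IDAT processing, read alignment).

## Problem sizes and runtime

Default test and acceptance runs use 5,000 blocks × 4 probes × 27
samples and 10,000 peaks (the full pipeline in well under two minutes on
one CPU); the determinism check uses a 600-block bundle run twice
through all seven stages. These sizes are the package's documented desk
scale; genome-scale inputs (~500k blocks) stream through the same code
paths linearly.

## Known limitations

* The JT Edgeworth refinement applies only to tie-free data; heavily
  tied blocks fall back to the plain corrected normal, which is slightly
  less accurate at very small groups.
* Per-sample BMIQ on data that is not mixture-shaped introduces small
  sample-specific distortions (see above); pooled normalization is not
  implemented.
* `hierarchical_cluster` requires complete rows; there is no
  pairwise-complete distance mode.
* The purity estimator assumes binary marker states; partial
  methylation in tumor cells biases estimates downward unless
  calibration is used.
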