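# Methods

`nestkin` quantifies how the foundational spermatogonial stem-cell (SSC)
pool is established in the neonatal mouse testis, using three measurement
modalities that are analysed by separate but interlocking pipelines: 3D
germ-cell nest statistics from whole-testis fluorescence volumes,
flow-cytometric gating with developmental-kinetics summaries, and scRNA-seq
clustering/annotation.  Because the underlying animal experiments are not
reproducible at desk scale, each pipeline is validated against seeded
synthetic data whose generative model is described below, with complete
ground truth.

## Nest detection and statistics

**Model.** A nest is a group of at least `min_cells_per_nest` (default 3)
germ cells in which neighbouring cells are separated by no more than
`cutoff_um` (default 10 µm).  Formally this is the single-linkage
hierarchical clustering of the inter-object distance matrix cut at the
cutoff — equivalently, the connected components of the graph joining
object pairs at ≤ cutoff.  Groups below the minimum cell count are treated
as chance proximity (two cells can sit together transiently after
division) and reported as singletons.

**Distances.** Germ cells average ~20 µm in diameter, so a 10 µm
*surface* separation is the geometrically meaningful reading of the
cutoff: with centre-to-centre distances, two non-overlapping 20 µm cells
could never satisfy it.  The default `distance_mode="border"` therefore
subtracts the equivalent-sphere radius of each object (from its measured
volume) from the centroid distance, flooring at zero for overlapping
objects; `"center"` (plain Euclidean) is retained as an option.  Ties at
exactly the cutoff are included ("no more than").

**Cell counting.** Detection does not split touching cells; instead each
object's volume is divided by the volume of a reference 20 µm sphere
(~4189 µm³) and rounded, clamped to ≥ 1.  These estimated counts feed both
nest size and the minimum-cell rule.  A nest's intensity class is assigned
from its (cell-count-weighted) mean eGFP intensity, not by member vote.

**Summaries.** Per intensity class: percent of cells in nests
(denominator = all detected cells of the class, nested or not), average
nest size in cells, and total nest count.  When only part of an organ
could be imaged, the total nest number is extrapolated by
`observed × FCA_total / imaged_cells`, using the class's total cell count
from flow-cytometric analysis (FCA).

**Edge correction.** Partial-depth imaging truncates cells at the last
optical section: their measured volumes (hence equivalent radii and
estimated counts) shrink and edge nests split, biasing the scaled estimate
downward.  `apply_depth_guard` excludes objects whose centroid lies within
one cell diameter of the imaging limit before nest calling — the same
logic as an unbiased counting frame in stereology.  In simulation this
removes a ~10% downward bias, leaving the mean scaled estimate within a
few percent of truth.

## Object detection

Stacks are strongly anisotropic (1 µm pixels, 5 µm optical sections), so
all measurements are in physical µm; voxel centres sit at
`(i + 0.5) × voxel_size`.  Detection thresholds default to Otsu computed
on log1p intensities of nonzero voxels (fluorescence spans decades and the
background class vastly outnumbers signal; linear-scale Otsu tends to
split the signal modes instead).  When the resulting foreground exceeds 5%
of the volume — the signature of Otsu degenerating onto the noise
distribution in nearly-empty stacks — the threshold is re-estimated within
the foreground, up to three times.  Connected components use
26-connectivity by default (diagonal contacts matter at coarse z-steps)
and a minimum object volume of 500 µm³ removes noise specks.  Both are
configurable; the original analysis software's settings are not public, so
these defaults are declared choices, not inferred ones.

Interstitial autofluorescent blobs appear in the reporter (eGFP) channel
only; when a lineage-label (tdTomato) channel is supplied, objects without
co-channel signal above threshold at their centroid are discarded.

## Cytometry gating and kinetics

Germ cells are gated as events above the 99.5th percentile of the
unstained-control tdTomato distribution.  This is a quantile rule, so
events drawn from the background distribution itself pass at ~0.5% by
construction; subset-recovery checks are therefore made on truth-germ
events.

For each sample, the eGFP⁺ range (positivity threshold → sample maximum)
is divided into three equal-width bins on log10 scale — Dim, Mid, Bright
from low to high; values exactly at a cutpoint go to the higher bin.
Per-sample (not pooled) boundaries are used, and the log scale is the
default because cytometry intensities span decades; a linear option
exists.

DNA-content analysis locates the 2N mode as the lowest prominent histogram
peak and classifies events above `1.5 × mode` — the midpoint of the 2N
and 4N positions — as S/G2/M.  This threshold rule is deliberately
assumption-light compared with two-Gaussian fitting; its known cost is
that early-S cells below the midpoint are assigned to G0/G1, so the
estimate is downward-biased by half the S-phase share of the cycling
pool (see the generator notes for how the synthetic model bounds this).

The kinetics table assembles per-age subset counts into absolute
cells/animal (a user-supplied events→cells factor), percent of germline,
fold-change versus the previous age, and a plateau flag raised at the
first age opening `plateau_run` (default 2) consecutive intervals whose
fold-changes stay within `plateau_tol` (default 0.15) of 1.  The plateau
definition is artifact-defined; plateaus are described qualitatively in
the source material.

## scRNA-seq analysis

QC bounds are per library and strictly inequalities (a cell exactly at a
printed ">1300 genes" or "<25%" mitochondrial bound fails).  Germ cells
are selected by summed Dazl/Ddx4 counts ≥ 1.  Normalisation is
counts-per-`scale_factor` then log1p; per-gene scaling is z-scoring across
cells with zero-variance genes zeroed and flagged.  Variable genes:
dispersion (variance/mean of normalized expression) z-scored within
equal-frequency bins of mean expression; genes above the z cutoff are
kept.

Clustering embeds scaled cells in PCA space (fixed `n_pcs`; principal-
component significance testing is out of scope), joins each cell to its
`k` nearest Euclidean neighbours, and optimises modularity (RB
configuration model, Leiden implementation) at a given resolution with a
fixed seed; labels are relabelled by decreasing cluster size.

**Resolution criterion.** The biologically anchored rule is that a known
reference population (e.g. the P6 SSC pool, ~10% of the germline) should
be *enriched within a single cluster*.  For each resolution on a grid we
find the cluster containing the largest share of the reference and score
containment (share of reference inside) and purity (share of cluster that
is reference); the smallest resolution with containment ≥ 0.8 and purity
≥ 0.5 is selected and the full scan table is always reported.  If no
resolution qualifies the selector raises an error carrying the table.

Marker ("dotplot") statistics are the per-gene, per-cluster mean
normalized expression z-scored *across clusters* (the dotplot convention;
whether the original scaling was across clusters or cells is not stated)
together with the detection fraction (share of cells with a nonzero raw
count).  The marker criterion is scaled expression > 0 and detection >
10% within at least one cluster, strictly.  Cluster identities are scored
as mean scaled expression over marker panels; the SSC-like cluster
maximises (SSC score − differentiation score), with the whole score table
returned rather than hidden thresholds.

Replicate agreement uses the modified RV coefficient: column-centred
configuration matrices XXᵀ and YYᵀ with their diagonals zeroed (removing
the self-similarity inflation of the plain RV), correlated under the
Frobenius inner product.  The replicate unit is a pseudobulk profile
(per-gene mean normalized expression per library); the original feature
space is not specified, and pseudobulk is the declared choice.

Omitted relative to the original software stack, as declared scope
decisions: covariate regression during scaling, PC significance testing
(fixed `n_pcs` instead), tSNE/UMAP embeddings, and pseudotime machinery.

## Synthetic-data generators

All generators are pure functions of a config and an integer seed
(identical inputs give bit-identical outputs) and return complete ground
truth.

**Volumes.** Germ cells are uniform-intensity solid spheres — no PSF,
since nest statistics consume centroids, volumes and mean intensities
only — rasterized in physical µm on the anisotropic grid.  Tubule paths
run along x at constant (y, z), so a nest's members share one optical
depth and partial-depth imaging includes or excludes whole nests, as
nests along a tubule do in cleared tissue.  Nest members are chained at
surface gaps drawn from [3, 8] µm; distinct groups are kept ≥ 35 µm apart
(placement by rejection sampling with an explicit retry cap and failure).
Cell diameters are 20 ± 1 µm, truncated at ±2 sd: germ cells are uniformly
sized, and an unbounded tail would let a single large cell read as a
doublet under equivalent-sphere counting.  eGFP intensities are log-normal
per class (Bright median 250, Mid 80, sd 0.15 in log units — well
separated, as the two classes are the only ones confocal imaging resolves);
tdTomato is a shared constant; autofluorescent blobs (eGFP only) are
placed outside tubules; Gaussian background noise (sd 2) is added and
clipped at zero.  Defaults mirror the imaged study conditions: 400 × 400
× 200 µm volumes at (1, 1, 5) µm voxels with 8 Bright and 3 Mid nests
plus singletons.  Not emulated: optics (PSF, bleaching, depth
attenuation), tubule curvature, and cell shape variation — so passing
recovery tests demonstrates correctness of the measurement chain, not
robustness to optical artifacts.

**Flow events.** Germ subsets draw log10-eGFP uniformly from disjoint
bands aligned to equal thirds of the positive range with a 10% margin
inside each third; the margin guarantees that per-sample tertile
boundaries (which depend on the random sample maximum) cannot cross a
band.  tdTomato is log-normal around 10³ for germ cells and matches the
unstained-control background for non-germ events.  DNA content is the
standard univariate model: a 2N peak (mode 100, CV 5%), a 4N peak at
twice the mode, and an S-phase bridge uniform between them.  Within the
cycling (S/G2/M) pool the S-bridge share is `s_phase_share = 0.05` with
the remainder at 4N; since the midpoint threshold assigns the lower half
of the bridge to G0/G1, this share bounds the estimator's structural bias
at `f × s/2` ≤ 0.0125 — the regime in which the threshold classifier is a
faithful readout of the cycling fraction.  KIT labels are Bernoulli per
subset with log-normal positive/negative intensities.

**Count matrices.** Each cell has a latent continuum position u ∈ [0, 1].
An SSC program (8 genes) has expected expression decreasing in u and a
differentiation program (8 genes) increasing, each spanning a 2-log2-fold
range by default; housekeeping genes (including Dazl/Ddx4) are constant
and high.  A rare population (10%, assigned deterministically as
`round(fraction × n)` cells per age) sits at the low-u end and expresses a
dedicated 20-gene marker set 4 log2-fold above baseline.  Counts are
negative binomial (dispersion 10) over log-normal library sizes (~5000),
with mitochondrial genes absorbing a per-cell Beta(2, 30) fraction of the
library and optional extra dropout (5%).  Optional planted low-quality
cells (mito 0.30–0.60, 5× shallower libraries) and Dazl/Ddx4-free somatic
cells exercise QC and germ selection.  The generator works at the matrix
level; read-level artifacts (ambient RNA, doublets, UMI saturation) are
not emulated.

## Problem sizes and numerical choices

Validation runs use 20 seeded volumes for planted-nest recovery and
depth-scaling consistency, 100 random point sets (≤ 500 points) for the
nest-caller/graph-components equivalence, 10,000 events per cell-cycle
recovery, and 10 seeds of 1,000 cells × 500 genes for
resolution-selection recovery — sizes chosen so the full suite completes
in about a minute while keeping Monte-Carlo error well inside the asserted
tolerances.  Deterministic orderings are fixed throughout (objects by
first-voxel scan position, nests by minimum member id, clusters by
decreasing size) so identical configs and seeds reproduce identical bytes;
the pipeline runner stamps every output table with a hash of its config.

## Known limitations

- Border distances use equivalent spheres, which misestimate gaps for
  strongly aspherical or merged objects.
- The 2N-mode peak finder assumes the 2N population is present and
  non-negligible; aneuploid or heavily debris-contaminated histograms are
  out of scope.
- The resolution selector optimises for one reference population; data
  with several rare populations may need a different criterion.
- Generator realism is deliberately minimal (see above); none of the
  defaults are calibrated to the deposited animal data.
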