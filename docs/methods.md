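# Methods

`organomorph` quantifies the morphodynamics of epithelial organoids imaged
by dual-channel 3D+t light-sheet microscopy: how the tissue and its
fluid-filled lumens grow and fuse, what shapes the sparsely labelled cells
take, how those cells orient relative to the organoid surface, and how
coherently they move.  Because raw light-sheet recordings of this kind run
to terabytes and are rarely shareable, every stage is driven and validated
by a synthetic 4D scene generator with complete ground truth.  This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic validation does and does not establish.

## Coordinate and unit conventions

Arrays are indexed `(z, y, x)`, 0-based; physical position = index ×
spacing.  All distances are micrometres, volumes µm³, time in hours.
Default voxel spacing is anisotropic, (2.0, 1.0, 1.0) µm, mirroring the
coarse axial sampling of light-sheet stacks.

## Synthetic scene generator (`synthgen`)

The scene is a ball-shaped organoid whose radius follows a per-frame
schedule, containing (i) lumens — balls with per-frame radius schedules and
an explicit fusion schedule — and (ii) cells of five label classes
multiplexed into two channels: GFP carries actin and histone, RFP carries
lamin, membrane and tubulin.  Classes differ by construction in size,
elongation and topology: histone is a small filled blob, actin and tubulin
are elongated filled ellipsoids (axis ratios ~0.32 and ~0.22), and lamin
and membrane are hollow ellipsoidal shells with a 2-voxel wall, giving them
the distinct surface-to-volume and solidity signatures a demultiplexer can
learn.  An optional sixth population of small irregular debris blobs
("faulty") provides training examples for the classifier's reject class.

Lumen fusion is realized *geometrically*: radius schedules are required to
make the two partners' masks touch at the scheduled frame (the generator
raises if they do not, or if two lumens touch without a scheduled fusion),
so the tracker must detect fusion from mask overlap rather than from a
relabelling convention.

Cells are placed by rejection sampling: candidate centres are voxels whose
anisotropy-aware distance to the nearest non-tissue voxel exceeds the
cell's bounding radius (so the cell stays inside tissue in every frame),
and a voxelized occupancy test rejects overlap with already-placed cells
with one voxel of clearance.  Elongated cells (actin, tubulin) are oriented
along the analytic outward normal of the generating sphere with probability
`radial_fraction`; the remainder are uniformly random or, optionally,
tangential (used to produce a negative control for the alignment index).
Cells may perform a bounded random walk (`cell_jitter_um` per frame) that
never leaves the persistent-tissue region.

Frames are corrupted by cumulative integer drift (`drift_per_frame`,
applied with zero fill) and additive Gaussian noise.  The noise model is
intentionally plain — no Poisson shot noise, PSF blur, bleaching or
attenuation — because denoising is outside the package's scope; `noise_sd`
is a robustness dial, not a camera model.  Consequently, passing tests
demonstrate the *algorithms* are correct on data obeying their geometric
assumptions; they do not certify performance on raw microscope data, where
segmentation quality, debris and optical artefacts dominate.

Fixed study scenes (factories in `synthgen`) define the validation
conditions: a 12-frame four-lumen scene with fusions scheduled at frames 3,
6 and 9 and all lumen radii ≥ 18 µm (so every lumen clears the 20,000 µm³
volume threshold); a drift scene with (1, 2, 3) voxels/frame over 10
frames; a five-class mosaic scene (20 cells/class + 12 debris, 4 frames);
single-frame isotropic scenes of radially or tangentially oriented actin
cells on a 42 µm sphere; and a tracklet scene of ten ~2,600 µm³ wandering
cells.  Scene sizes (≤ 84×168×168 voxels) were chosen once as the desk
scale at which every geometric regime of the analysis (fusion necks,
anisotropy, thresholds) is still represented.

## Temporal registration (`register`)

Pairwise translations are estimated as the mean 2D phase-cross-correlation
shift of the three axis-wise maximum-intensity projections (each axis is
covered by two projections; the two estimates are averaged).  Per-frame
offsets are composed from all frame pairs inside a sliding window of 3
consecutive frames.  How multi-frame pairwise estimates combine into one
offset per frame admits several readings; the scheme implemented is: a pair
(i, j) measures the summed drift over steps i+1…j and contributes its mean
per-step increment to every step it spans; per-step increments are averaged
over all covering pairs, cumulatively summed, and rounded to integers.
This reproduces constant drift exactly and bounds the influence of a
single outlying pairwise estimate by 1/window per step.  Offsets are
applied as pure integer shifts (no interpolation) to all channels and
masks, with zero padding sized so no voxel is lost.  Rotation and subvoxel
registration are out of scope; the GFP channel leads by default.

## Tissue segmentation and quantification (`tissue`)

A pixel-wise random forest (50 trees, depth 25, per-tree subsample 0.05)
classifies each z-slice of the summed two-channel image into background,
lumen or tissue, using multiscale basic features (Gaussian intensity,
gradient magnitude, Hessian-eigenvalue texture) on the geometric sigma
ladder 1…64 → 28 features/pixel.  Training pixels come from sparse
single-class boxes; on synthetic scenes these are sampled automatically
from pure-class neighbourhoods of the ground truth.

Post-processing: per-class Gaussian smoothing at an isotropic physical
sigma of 2.776 µm (divided by the per-axis spacing) with argmax
recombination; then per z-slice, lumen closing with a radius-3 disk, lumen
hole filling, background enclosed by the organoid reassigned to lumen, and
lumen outside the 2D convex hull of the tissue reassigned to background
(in that order — the ordering of hole-filling versus reassignment is a
documented choice); finally only the largest connected non-background
component is kept.  Time series of lumen masks are stabilised by a
temporal median filter (window 5 frames), 4 iterations of binary opening,
and removal of connected components below 20,000 µm³ (strict inequality).
On clean ground-truth masks — e.g. when checking that the lumen-count
series equals births minus realized fusions — the binary opening is
disabled: it exists to suppress false fusion necks in noisy predicted
masks and would otherwise briefly re-split a genuinely fused cavity whose
neck is still thin.

Quantification reports per frame the organoid volume (tissue ∪ lumen voxel
count × voxel volume) and per-lumen volume and major axis length from
second moments, all in physical units.

## Morphometrics and demultiplexing (`morpho`)

Instance masks are resampled (nearest-neighbour; intensities linearly) to
an isotropic 0.694 µm working voxel, and instances under 100 voxels
(33.4 µm³) are discarded.  Per instance: volume, marching-cubes surface
area, major/minor axis lengths and their ratio, sphericity
(π^⅓(6V)^⅔/A), solidity, intensity mean/max/SD, centroid, and inertia-
tensor eigenvalues.  QC removes rows with volume < 100 voxels, maximum
intensity < 20 (both strict), or any missing value, and logs counts per
reason.

The demultiplexer is a random forest over all QC-passing morphometrics
plus a channel indicator, grid-searched by 4-fold cross-validation over
trees ∈ {50, 100, 200} × depth ∈ {5, 10, 20, ∞} on a stratified 90 %
training split, with accuracy reported on the held-out 10 %.  A stratified
5-fold retraining produces a summed confusion matrix; per-marker precision
is computed after excluding the faulty class.  Predictions incompatible
with the structure's channel (GFP → {actin, histone}; RFP → {lamin,
membrane, tubulin}; faulty allowed in both) are removed.  On the separable
synthetic mosaic the held-out accuracy is ≥ 0.9 by design; that figure
validates the pipeline's plumbing, not the much harder real-microscopy
problem, where accuracy is limited by segmentation quality.

## Shape statistics (`shapes`)

*Ellipsoid fit.*  Surfaces of individual cell masks (marching cubes, step
2) are fitted with the 9-parameter algebraic least-squares quadric
x'Ax + 2b'x = 1; centre −A⁻¹b, radii and axes from the eigen-decomposition
of the recentred quadric.  Fits with < 10 points, coplanar points,
non-positive eigenvalues, or any radius above 180 point-units (≈ 125 µm at
the 0.694 µm working voxel) are flagged invalid rather than raised.

*Alignment index.*  The organoid surface is meshed by coarse marching
cubes (step 4 at desk scale; a knob for larger volumes), cleaned, its
normals repaired to point outward, and Taubin-smoothed for 50 iterations.
The index is |cos| between the cell's fitted major axis and the outward
normal at the mesh vertex nearest the cell centroid (KD-tree lookup):
1 = radial, 0 = tangential.  Cells whose fitted axis ratio exceeds 0.9
are orientation-degenerate (a sphere's major axis is arbitrary) and are
excluded from alignment summaries, with counts reported.

*Morphotype clustering.*  Non-intensity, non-positional morphometrics plus
the axis ratio are z-scored, reduced to 5 PCs (4 for all-marker runs),
embedded in a 15-NN graph and Leiden-clustered (resolution 0.6 by default;
seeded).  The cluster graph keeps edges whose PAGA connectivity is ≥ 0.1;
a fully disconnected quotient graph is handled explicitly.  An optional
seeded, graph-initialised UMAP provides 2D coordinates for reporting only
— no result depends on them.  For the deliberately bimodal two-population
fixture the tests use resolution 0.05, the merge scale at which Leiden
reports the two modes as two communities rather than subdividing them.

*Diversity.*  Shannon index H′ = −Σ pᵢ log₂ pᵢ with 0·log 0 ≡ 0; per
condition-day cluster proportions; stratified bootstrap (resampling
structures with replacement within each condition-day, B = 1000 by
default) for 95 % percentile confidence intervals, with strata of fewer
than two structures flagged.

## Tracking (`tracking`)

Detections per frame become nodes scored 1 − min_vol/volume (min_vol:
20,000 µm³ for lumens, 481.6 µm³ for cells; negative scores deter the
selection of undersized detections).  Edges join detections in consecutive
frames within a maximum centroid distance (1,110 µm lumens, 24.3 µm cells,
anisotropy-honouring physical distances).  Lumen edge score = max(overlap/
volumeᵢ, overlap/volumeⱼ); cell edge score = ½[(1 − d/max_d) + IOU], where
the IOU is the positional intersection-over-union of the two masks within
their joint bounding region — so two non-overlapping cells at exactly the
maximum distance score 0 and the edge is dropped, as are all zero-score
edges.  Cell masks below 1,444 µm³ are discarded before graph
construction.

Selection is an exact 0/1 ILP (HiGHS): minimise Σ(−node score) +
Σ(−edge score) + 0.8·(appearances) + 0.8·(disappearances) subject to
degree caps (≤ 2 parents/children for lumens — a node with two selected
parents *is* a fusion event; exactly ≤ 1/1 for cell tracklets, which
therefore cannot branch).  An appearance is a selected node after the
first frame with no selected in-edge; no boundary costs are charged at the
movie's first/last frame, so objects spanning the movie are not
penalised.  Solutions are binary, making the 0.5 acceptance threshold on
solution values a pass-through.  A vectorised brute-force enumerator over
all feasible edge subsets (isolated nodes included when their standalone
contribution is negative) provides an independent optimum for graphs with
≤ 16 edges; solver and enumerator agree exactly on 1,000 random small
instances.  Fusion extraction reports the event table, per-frame counts
smoothed by a rolling mean (window 10, min periods 1), and hours-since-
fusion as shortest-path distance along the track graph, capped at 10
frames.

## Motion statistics (`motion`)

The radial coordination score of a cell at frame t is the cosine between
(centroid − organoid centre of mass) and the velocity over the preceding
24 h of its track (+1 outward, −1 inward); zero-velocity samples are
excluded and counted.  The centre of mass comes from the organoid
semantic mask by default (any per-frame COM table can be supplied).  Note
the estimator has a small positive bias for diffusive motion — the current
position enters both vectors — of order step·√(3L)/r₀; at organoid scale
(r₀ ≈ 40 µm, sub-µm hourly steps) this stays below 0.05, which is the
regime the isotropic random-walk control verifies.  Velocity fields for
display smooth centroids with a rolling mean (window 10, min periods 1)
and take displacement over the previous 5 frames; z- and xy-direction
angles (atan2) are min-max normalised to [0, 1] in export tables.

## Pipeline and provenance (`config`, `pipeline`, `cli`)

A single YAML-serialisable configuration carries every stage parameter
with the reference defaults above; its SHA-256 hash is embedded in each
stage's completion marker, and outputs are byte-identical across reruns
with the same seed.  Stages are cached and resumable: deleting one stage's
outputs recomputes it and everything downstream.  The bundled demo
configuration scales the scene (and the volume thresholds, which would
otherwise exceed the demo organoid itself) down so the full chain runs in
well under a minute; all reference values remain the package defaults.

## Known limitations

- The generator's optics are idealised (no PSF, shot noise, bleaching,
  scattering); segmentation accuracy on synthetic scenes is an upper bound.
- Instance segmentation of cells is consumed, not produced: real use
  requires an external 3D instance segmenter.
- The ILP is exact but exhaustive validation is only feasible for small
  graphs; larger instances rely on the solver's optimality guarantee.
- Sequential frame-to-frame registration against a reference frame (the
  variant used for very long recordings) is exposed only as the same
  offsets interface, not implemented.
- Morphotype clusters are resolution-dependent, as Leiden clusters always
  are; the cluster graph and diversity statistics should be read at the
  chosen resolution, not as an absolute taxonomy.
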