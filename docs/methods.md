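# Methods

## Scope and model

`treebench` evaluates a reconstructed 3-D point cloud ("model") against
a reference cloud of the same scene. The reference here is synthetic and
fully labelled, so every evaluator can be scored against exact ground
truth; the evaluators themselves are generic and accept any pair of
clouds in the supported formats. The chain is: similarity alignment →
one-sided nearest-neighbour distance fields → octree connected-component
artefact census → voxel-level ROC/AUC.

All lengths are in *scene units* — whatever unit the reference uses. No
unit is enforced; every relative threshold is normalised by the *scene
width*, defined as the larger of the x- and y-extents of the reference
bounding box.

## Synthetic reference scene

The generator emulates a single-tree survey plot at the point-cloud
level (no imagery, no rendering):

* **Tree** — a recursive branching skeleton: each node spawns
  `branches_per_node` children (default 3) tilted `branch_angle_deg`
  (35°) from the parent with evenly spaced, seed-jittered azimuths, and
  lengths shrinking by `branch_length_ratio` (0.6) down to
  `branching_depth` (4). The skeleton is grown with a unit trunk and
  rescaled so the highest tip sits exactly at `tree_height` (default 16
  units, a typical mature deciduous tree). Points are sampled on the
  trunk/branch cylinder surfaces at the common surface density and in
  ellipsoidal foliage blobs at the terminal tips. Foliage density
  (`foliage_points_per_tip` = 400 in blobs of semi-axes ~0.7 units) is
  chosen so each blob, and the tree as a whole, is one 26-connected
  component on a level-8 octree grid — the reference must segment as a
  single main structure, which is a contract the tests enforce.
* **Ground** — a regular grid over `ground_extent`² (default 40², wide
  enough to contain a 20-unit-radius flight circle) with
  `points_per_unit_area` = 60 (grid spacing ≈ 0.13, below the level-8
  voxel edge so the ground stays connected) and Gaussian z-texture
  (`grass_noise_sd` = 0.03) imitating grass.
* **Targets** — eight cubes (edge 0.5) at 70% of the ground half-extent,
  evenly spaced in azimuth, each with a distinct label (10–17) and a
  distinct saturated colour. Cube surfaces are sampled *antipodally*
  (each random point paired with its mirror through the centre) so the
  returned centroid equals the point mean to 1e-9 — the alignment path
  treats those centroids as exact. Cubes sit slightly sunk into the
  ground so contact survives coordinate quantisation on write.

A single integer seed fixes the whole scene; the default scene has
~1.4×10⁵ points and writing it twice yields byte-identical PLY files.

## Artefact injection

`DegradeSpec` parameterises the defect classes observed in
software-derived vegetation reconstructions; the all-default spec is the
identity. Operators apply in a fixed order — omission → thinning →
jitter → ghost → attached ring → floating clusters → pose perturbation —
so noise never blurs injected artefact geometry and misalignment is
outermost. A manifest records every artefact's label and geometry plus
the achieved omission fractions.

Notable choices:

* **Omission** is two-part: spherical holes centred on random vegetation
  points (spatially coherent, like missing crown sections) and random
  point removal until the requested fraction of tree points is gone.
  Random ("salt") removal is *invisible* to any distance-based census —
  surviving neighbours sit within any reasonable matching radius — so
  recovery experiments drive omission through holes with radius well
  above the census gap (2.5 vs ~0.15–0.3).
* **Floating clusters** are Gaussian blobs (default 200 points,
  sd 0.12) in a sky box above the crown. Centres keep at least two
  cluster diameters (diameter := 6·sd) from each other and from the
  scene; with the default level-8 voxel edge (~0.156 at scene width 40)
  that guarantees voxel-disconnection, so the injected count is exactly
  recoverable.
* **Attached ring** — the classic horizontal sky-ring enveloping the
  upper crown. By default its major radius interpenetrates the foliage
  surface (the ring merges with the main component, i.e. it is
  physically attached); with `ring_gap > 0` it hovers that far off the
  crown instead, producing a separate cluster classified *attached*
  when the gap is below the classification threshold.
* **Ghosts** copy one labelled component at a rigid offset with a fresh
  artefact label, mirroring duplicated trunks from camera-pose errors.

## Alignment

Closed-form least-squares similarity fit (SVD of the centred covariance
with the determinant correction, scale from the singular-value sum over
the source variance). Scale *is* estimated — photogrammetric
reconstructions have arbitrary scale. Correspondences come from the
eight target centroids (by label) or an explicit list. Optional ICP
refinement alternates nearest-neighbour matching (cutoff 5% of scene
width, so artefact points cannot drag the fit) with the closed-form fit,
returns the best iterate, and documents a convergence basin of roughly
an initial RMS below 5% of scene width. From 8 noisy centroids (noise
sd = 10⁻³ scene width) the median recovery error is ~0.05% in scale,
~0.09° in rotation and ~0.05% of scene width in translation over 100
random similarity transforms.

## Distance fields and classes

`nn_distances` is exact (scipy cKDTree, no approximation) and one-sided:
model→reference exposes commission, reference→model exposes omission.
Distance classes follow the conventional five-colour map on distances
relative to unit scene width: class edges at 0.0075, 0.015 and 0.0225
with half-open [lower, upper) bins, a fourth class up to twice the last
edge and purple outliers beyond. The outlier cutoff (2×0.0225) is this
package's choice; the first three edges are the conventional values.

## Octree connected components and census

The cloud is voxelised at octree level L on its *own* bounding box
(voxel edge = largest extent / 2^L; the conventional setting is L = 8),
occupied voxels are linked under 26-neighbour connectivity (the least
fragmenting choice; stated in every report) and components below
`min_cluster_points` (default 10) are reported as residue. The largest
cluster is *main* (ties → lowest cluster id, with a warning); other
clusters are *attached* when their minimum point distance to main is at
most the gap threshold (default twice the voxel edge), else *floating*.

The census adds the omission fraction: the share of reference points
farther than `omission_gap` from any model point, overall and restricted
to vegetation labels. `omission_gap` defaults to the gap threshold; for
noise-free models a value near the reference point spacing (~0.15) is
sharper, and recovery of hole-driven omission is then accurate to ~0.02.
The hole-boundary shell (removed points within the gap of survivors)
biases the measurement low by roughly gap/hole-radius; the tests bound
the total error at 0.05.

## ROC construction

The 2×2 table needs a well-defined negative class, which raw point sets
do not provide. Space is discretised into voxels (default size = scene
width / 256, consistent with the level-8 census) over the reference
bounding box padded on every side by 10% of its largest extent, so sky
artefacts fall inside the negative class. The *positive* class is the
set of voxels whose centre lies within the ground-truth radius — half
the voxel diagonal — of at least one reference point; every other voxel
is negative. At threshold r the model predicts positive at voxels whose
centre lies within r of at least one model point; at r = 0 the predicted
set is empty. TP/FP/FN/TN follow, TP+FN and FP+TN are constant along the
sweep by construction, and TPR/FPR are non-decreasing in r (dilation
monotonicity).

This construction satisfies the three anchor properties of the
statistic: the curve passes through (0,0) at r = 0; through (1,1) once r
exceeds the scene size; and a flawless model passes through (0,1)
exactly, because at r = ground-truth radius its predicted set coincides
with the positive set. The curve is anchored with the r = 0 table and
the saturated table, and AUC is the trapezoidal integral over the
(FPR, TPR) polyline sorted by FPR with ties keeping the maximum TPR,
clamped to [0,1] (cross-checked against scikit-learn's integrator in
the tests).

**Radius sweep.** 64 values from a quarter voxel to the scene diagonal:
a dense geometric sweep up to 16 voxels — the knee of the curve, where
all the shape information lives — plus a 10-value geometric tail to the
diagonal. In the tail the true-positive rate has saturated and FPR
varies smoothly, so coarse sampling loses essentially nothing, while
each tail radius costs ~10⁵ exact far-field distance queries; the
knee-weighted allocation keeps a default evaluation of a 10⁵-point
scene under a minute on one CPU. The ground-truth radius is always
inserted so a flawless model hits (0,1) exactly.

A diagnostic point-based completeness/correctness pair is reported in
the full evaluation output but is not called ROC — without a negative
class it is not one.

**Exact voxel distances at scale.** The default grid has ~1.5×10⁷
voxels; per-voxel k-d-tree queries are prohibitively slow on
planar-heavy scenes. The engine instead brackets each voxel's exact
point distance with an exact Euclidean distance transform of the
occupancy grid (centre-to-centre distance e, half-diagonal h, true
distance in [e−h, e+h]), tightens the upper bound with the distance to a
representative point of the nearest occupied cell, and computes exact
distances only for voxels whose bracket straddles a sweep radius — via a
compiled cell-list search in the near field and batched dual-tree
nearest-neighbour queries in the far field. Every stage is exact; the
tests verify bit-equality of the resulting confusion counts against a
dense brute-force scan on grids up to 64³.

## Default problem sizes

Chosen so the full default pipeline is desk-scale: reference ~1.4×10⁵
points (cap 2×10⁶), default ROC grid ~1.5×10⁷ voxels (~35 s per
evaluation on one CPU), and reduced-size scenes (extent 30, ~7.5×10⁴
points, voxel = width/64) for experiments that sweep many degradation
levels and seeds. Sweep experiments in the tests use 10 degradation
seeds per level.

## What the synthetic benchmark does and does not show

The generator produces labelled, noise-controlled clouds whose artefact
inventory is known exactly; passing tests therefore demonstrate that the
evaluators *measure what they claim* — alignment recovers known
transforms, the census recovers injected cluster counts and hole-driven
omission, AUC decreases monotonically in injected degradation, and all
computations are deterministic and oracle-exact. They do not show
anything about the photogrammetric pipelines themselves: real
reconstructions have spatially correlated noise, density gradients,
colour artefacts and background geometry distortions that the degrader
does not model (background issues are represented only as omission
holes). Published per-software AUC values depend on the authors'
specific scenes and reconstructions and are not reproducible from this
package; the benchmark ranks *simulated* defect profiles only.

## Degenerate inputs and numerical conventions

Empty model clouds are legal in the ROC path (TPR = FPR = 0 for all
finite r; the curve is the two anchors); empty references are errors.
Collinear or <3 correspondences raise a rank error in alignment.
Distance-class edges use half-open bins (an exact edge value falls in
the higher class). Cluster ids are assigned by decreasing size with
voxel-key tie-breaks, making segmentation invariant to point order.
PLY output uses 6 significant digits by default (configurable); all
randomness flows from integer seeds through `numpy.random.Generator`,
and identical seeds give byte-identical files and reports.
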