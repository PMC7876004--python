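# Methods

`wm3dseg` performs instance segmentation and morphometry of white-matter
ultrastructures in low-resolution (≈50 nm isotropic) 3D electron
microscopy.  At this resolution the axonal membrane is invisible at nodes
of Ranvier and the nuclear envelope is only partially resolved, so any
segmentation that starts from per-voxel class probabilities is prone to
*under*-segmentation: neighbouring axons merge into one connected
component, and touching nuclei merge into one blob.  The package takes the
opposite of the usual over-segment-and-merge strategy: it accepts the
merged components and *splits* them using strong shape priors — axons are
tubes, nuclei are near-spheres.

## Pipeline

1. **Pre-processing** (`preprocess`).  Serial-section stacks are aligned
   by FFT cross-correlation between consecutive slices (integer-voxel
   application, 1/4-voxel peak interpolation).  The applied correction is
   the cumulative shift minus its running average (window 25 slices,
   shrinking windows at the ends), so slice-to-slice jitter is removed
   while slow trends — the true obliqueness of axons through the block —
   survive.  Whitened (phase-only) correlation was rejected: on smooth,
   low-contrast EM slices it produces spurious ±1 voxel peaks where plain
   cross-correlation is exact.  Contrast normalization rescales every
   slice affinely to the global stack mean/sd; `to_uint8` converts by
   min–max with round-half-up.  Volumes can be tiled into non-overlapping
   patches (default target ≈1000×1000×300) and reassembled bit-identically.
   External denoising is an optional shell hook; the pipeline never
   requires it.

2. **Training-label engineering** (`trainprep`).  A high-resolution
   segmentation is converted to semantic training classes: unmyelinated
   axons and cell bodies are set to background for the axon class set; a
   nucleus-membrane class is created by a slice-wise 2D morphological
   gradient with a flat 11×11 square element (band width 2·⌊11/2⌋ = 10
   voxels — a plain dilation-minus-erosion band; a reported 22-voxel width
   would require applying the gradient to an already-dilated mask, so the
   element width is a parameter and the discrepancy is documented rather
   than guessed).  In-plane down-sampling uses the block mean for
   intensities and block majority vote for labels (ties toward the smaller
   class value), scaling the in-plane voxel size accordingly.

3. **Initial instances** (`initseg`).  Probability maps are binarized
   with strict `>` at θ_myelin = 0.5, θ_axon = 0.8, θ_mito = 0.8.  The
   intra-axonal space is the axon mask united with the mitochondria mask
   dilated by a 3×3×3 cube.  26-connected components are closed
   (3×3×3 cube, per component) and filtered at 4700 voxels — the volume of
   a circular cylinder of radius 0.25 µm and height 3 µm at 50 nm voxels
   (π·0.25²·3 / 0.05³ ≈ 4712).  The myelin mask needs no further
   processing.  A helper selects binarization thresholds on annotated data
   by minimizing VOI split + merge over a grid.

4. **Cylindrical shape decomposition** (`csd`).  See below.

5. **Nucleus segmentation** (`nuclei_gdm`).  See below.

6. **False-positive elimination** (`fpelim`).  Six shape features per
   candidate (volume, marching-cubes surface area, equivalent diameter,
   extent, solidity, principal-axis length) computed at one-third linear
   scale, z-scored, and classified by an SVM with the quadratic kernel
   ((x·y)/σ² + 1)².  (C, σ) are selected on a 13×13 log-uniform grid over
   [1e−6, 1e6] by 5-fold cross-validation — a deterministic, reproducible
   stand-in for a sequential model-based search of the same box.
   Leave-one-group-out evaluation trains on all but one animal group and
   scores precision/recall/F1 on the held-out group.

7. **Morphometry** (`morpho`).  Along each axon's skeleton, cross-sections
   are taken every 0.2 µm (excluding one local diameter at each end to
   avoid cap artifacts): equivalent diameter 2√(area/π) and eccentricity
   √(1 − (b/a)²) from the second-moment ellipse of the in-plane
   8-connected region.  Tortuosity τ = arc length / endpoint distance.
   Inter-mitochondrial distances come in two flavours: geodesic distance
   between consecutive projected centroids, and the shortest geodesic gap
   max(0, s_min(next) − s_max(prev)) between projected extents.  Axon
   density is V_axons/(V_myelin + V_axons); cell density is nuclei per
   unit volume.

8. **Evaluation** (`evalmetrics`).  Precision/recall/F1 on masks;
   VOI split H(A|B) and merge H(B|A) in bits; Wallace indices a/(a+b),
   a/(a+c); Rand index; adapted Rand error 1 − F(pair precision, pair
   recall) with zero-labeled reference voxels excluded.  Everything is
   computed from the joint contingency table; tests verify exact equality
   with brute-force pair enumeration and with an independent library
   implementation.

## Cylindrical shape decomposition

A merged object is decomposed in four stages, all in voxel units
(isotropic voxels assumed).

**Skeletonization.**  The interior Euclidean distance transform (EDT)
defines a cost field cost = (max(EDT)/EDT)⁴; geodesic paths on this field
hug the medial axis.  Starting from the global EDT maximum, branches are
traced (Dijkstra-style geodesic propagation with traceback) from the
farthest voxel not yet covered by the skeleton's inflated maximal balls
(coverage factor 1.5), each new path ending where it meets the existing
skeleton.  The attachment bookkeeping splits host branches, merges
degree-2 chains, collapses junction-junction stubs shorter than 1.5× the
local radius, and prunes tip branches shorter than their junction-end
radius (suppressing surface-protrusion spurs).  Branch polylines are
lightly smoothed to sub-voxel positions and carry interpolated
maximal-inscribed-ball radii.

**Partitioning.**  At each junction, incident branch ends are paired into
straightest continuations by exact minimum-cost matching with cost
Σ(1 − cos θ); continuations above 90° are forbidden, the number of pairs
is maximized first, and ties resolve deterministically.  End tangents are
estimated over the arc window [r_j, 3r_j] from the junction, because the
traced skeleton bends unreliably inside the junction blob itself.  Two
refinements matter for fused tubes:

* *Junction clustering.*  Tubes fused over an extended contact produce two
  nearby junctions joined by a bridge branch that runs through the shared
  blob and belongs to no single tube.  Junctions connected by a
  junction-junction branch of length ≤ 2(r_a + r_b) are treated as one
  super-junction; limb ends pair across the cluster and the bridge branch
  is left to the intersection region.  Without this, shallow-angle merges
  split one of the tubes in two.

**Decomposition intervals and critical points.**  For every junction on a
sub-skeleton, an arc window [α_e·r_j, α_s·r_j] (α_e = 1.5, α_s = 10) on
each side is walked *from the far end toward the junction* at 1-voxel
steps, so the running mean cross-sectional contour is seeded by clean
single-tube sections.  Contours are the boundary of the in-plane connected
region containing the skeleton point, resampled to 64 points by equal
angle about the centroid.  The first section whose normalized Hausdorff
distance H_ρ (symmetric Hausdorff between centroid-centred point sets,
divided by the running mean's mean radial distance) exceeds θ_H = 0.85
marks the critical point.  The *cut contour* carried forward is the
running-mean shape placed at the last clean section — the section just
before the trigger is already mildly distorted and would inflate the
reconstruction.  Junctions whose windows overlap on the same sub-skeleton
share one cut zone bounded by the outermost clean contours.

**Cutting, grouping, reconstruction.**  Every object voxel is assigned to
the sub-skeleton of its nearest skeleton sample; voxels whose nearest
sample lies inside a cut zone are withheld.  Because the traced skeleton
wanders inside the fusion blob, each sub-skeleton is first *rectified*: the
polyline inside a cut zone is replaced by a quadratic fitted to the
10-voxel clean flanks, which keeps both voxel assignment and the sweep on
the tube's own axis.  Each sub-skeleton is then continued through the
withheld region by a generalized cylinder: a linear homotopy between its
two cut contours (cyclically aligned by minimal summed point distance)
swept along the rectified center curve in parallel-transported frames, and
voxelized by in-plane polygon rasterization at 0.5-voxel resolution (the
contour is pulled inward by 0.55 voxel to cancel the half-voxel dilation
that point rounding would otherwise introduce; calibrated on analytic
cylinders and frusta to ≤5% volume error).  Output labels may overlap only
inside reconstructed intersections; leftover withheld voxels fall back to
their nearest sub-skeleton, so every input voxel carries at least one
label.

## Nucleus segmentation (geometric deformable model)

The membrane probability map is enhanced with a multi-scale Frangi filter
(scales 1–3 voxels, α = β = 0.5), rescaled to [0,1], subtracted from the
nucleus map, and thresholded at θ = 0.5; 26-connected components give the
initial nuclei.  The *primary deformation* erodes each component inward by
0.3 µm using the EDT, which breaks the thin necks that join touching
nuclei; the split pieces are relabeled and pieces ≤1000 voxels dropped.
The *secondary deformation* grows every seed back with a level-set front
for 300 iterations:

φ_t = g(x)·(|∇φ|₊ − w·κ|∇φ|),   g = 1 − PR_m, clamped to 0 where PR_m > 0.6

with an Osher–Sethian upwind discretization for the balloon term, central
differences for mean curvature, and a CFL-stable time step
min(0.45, 0.9/(2 + 6w)).  Multiplying *both* terms by the stopping
function is the geodesic form: fronts halt exactly on membrane evidence
instead of being braked early, while the curvature term stalls bulges
through membrane gaps (a bulge of radius a stalls when w·2/a ≥ 1).  The
default w = 2.5 voxel units stalls gap bulges up to ≈5 voxels while
letting nucleus-scale fronts (seed radii ≳8 voxels) advance; a literal
"speed = PR_m" reading is available behind `speed="membrane"` but is
near-zero inside nuclei and stalls immediately.  Fronts of different
labels never cross — first arrival claims a voxel, ties to the smaller
label — and a final sub-voxel finish assigns voxels the zero level set
passed within half a voxel.  The 300-iteration budget is itself a
safeguard: it bounds total front travel, limiting leakage through large
membrane gaps.

## Synthetic phantoms (study conditions)

The generator (`phantoms`) produces exactly the failure modes the
pipeline must fix, with full ground truth:

* **Axons** — generalized cylinders (radius 0.2–0.3 µm, ±10% smooth radius
  wobble, 0.15 µm myelin sheaths) around smooth center curves; a
  configurable fraction of pairs is fused at a contact (crossing angle
  controllable between 30° and 90°), where the myelin sheaths are erased
  over a sphere so the intra-axonal spaces form one connected component —
  the node-of-Ranvier failure mode.  Tangent-aligned ellipsoidal
  mitochondria (length capped at 0.4 µm within these small volumes) lie
  strictly inside axons.
* **Nuclei** — ellipsoids of radius 0.7–0.9 µm with 2-voxel membrane
  shells; touching pairs share a membrane-free contact window, and a
  configurable fraction of membrane voxels is deleted in contiguous
  patches (the discontinuous-envelope failure mode).  Nucleus radii are
  chosen so the volumes fit desk-scale grids while the 0.3 µm erosion and
  1000-voxel seed filter still operate in their intended regime; real
  glial nuclei are larger.
* **Probability maps** — ground-truth masks blurred by a Gaussian
  (σ = 0.6 voxels) and sharpened around the 0.5 contour (slope 4),
  emulating the near-binary, sub-voxel-transition scores a trained
  semantic segmenter emits; clipped noise (sd 0.05) is added and per-voxel
  class sums renormalized to ≤1.  At the default thresholds the binarized
  classes overlap truth at IoU ≥ 0.9 and per-voxel argmax recovers ≥95% of
  labels.
* **Drift stacks** — a z-correlated random texture resliced with recorded
  per-slice positions = trend + i.i.d. integer jitter; the unshifted
  reference stack accompanies the shifts for residual checks.

What the phantoms do **not** emulate: real EM texture and organelle
content, anisotropic voxels, unmyelinated axons (unresolved at this
resolution by assumption), membrane-signal gradients within a sheath, or
the correlated failure modes of an actual network's probability maps.
Passing the phantom suite therefore demonstrates the correctness of the
geometry pipeline under its stated assumptions, not end-to-end accuracy
on tissue.

## Numerical choices and limitations

* Axis order (z, y, x), 0-based; world = index × voxel size.  Foreground
  connectivity 26, background 6; in-plane cross-sections 8-connected.
* Strict `>` at all probability thresholds; instance labels assigned in
  decreasing size order; all tie-breaks deterministic, so reruns and
  worker counts produce byte-identical outputs.
* The skeletonizer assumes isotropic voxels; anisotropic stacks should be
  resampled first.
* Contour resampling by equal angle assumes roughly star-shaped sections;
  strongly non-convex cross-sections are approximated.
* Alignment suppresses i.i.d. jitter by ≈3× (to ≈0.6 voxel rms), limited
  by the running-average subtraction itself (the window-25 mean of i.i.d.
  jitter has sd ≈0.4 voxel and is preserved by design) and by
  integer-voxel application; a hard 0.5-voxel residual bound is not
  attainable under these conventions.
* Problem sizes in the test suite and acceptance script (64³–96³ phantom
  volumes, 5–10 seeds per sweep, 300 level-set iterations) were chosen so
  the geometry operates in the same regime as the target data (tube radii
  4–6 voxels, nucleus radii 14–18 voxels) while whole sweeps remain
  reproducible on a laptop.
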