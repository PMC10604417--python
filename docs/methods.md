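# Methods

## Overview

`spikect` reconstructs and measures cereal spikes (barley is the design
target) from micro-CT scans without destroying the specimen.  A scan
arrives as an ordered stack of 8-bit transaxial slice images with a known
isotropic pixel size P (µm).  The pipeline is:

1. **Holder removal** — every slice shows the bright ring of the plastic
   specimen holder; pixels at or beyond a circular region of interest are
   zeroed.
2. **Per-slice segmentation** — a UNet predicts a binary grain mask per
   slice; the prediction is then used as a mask for Otsu thresholding of
   the *original* intensities, and only in-mask pixels above the threshold
   survive.  This "mask-assisted" step removes network false positives
   whose underlying intensities are background-level, and its output is by
   construction a subset of the predicted foreground.
3. **Stacking** — the per-slice masks become a single binary volume
   ("virtual spike"), stored as NIfTI with the voxel spacing P/1000 mm
   recorded in the header.
4. **Grain isolation** — each foreground voxel center becomes a 3D point;
   DBSCAN density clustering separates the grains (radius `eps` in voxels,
   working range 3–7; clusters below `min_cluster_voxels` points are
   discarded as debris).
5. **Morphometry** — per grain: volume V = n·P³/10⁹ mm³ from the voxel
   count n; surface S = m·P²/10⁶ mm² where m is the triangle area of an
   alpha-shape mesh over the grain's contour shell; length ≥ width ≥
   thickness from a principal-axes oriented bounding box.  Per spike:
   grain count, bottom-up grain positions, spike length, trait totals, and
   positional trait profiles across a population.
6. **Validation statistics** — squared Pearson correlation of virtual
   vs. manual trait values, and pairwise Welch t-tests between germplasm
   groups with the usual star annotation.

## Segmentation network

The network is the classic UNet shape: `depth` resolution stages (default
4), two 3×3 same-padded convolutions + ReLU per stage, 2×2 max-pool
downsampling, nearest-neighbour upsampling followed by a 3×3 convolution,
skip concatenation, and a 1×1 output convolution producing one logit per
pixel.  Channel width starts at `base_channels` (default 16) and doubles
per stage.  Input dims must be divisible by 2^depth; prediction pads by
reflection and crops when they are not.

Training minimizes binary cross-entropy on logits with Adam
(lr 10⁻³, β = 0.9/0.999), default 40 epochs and batch size 4, and returns
the parameters of the epoch with the lowest mean training loss rather than
the last epoch.  The implementation is plain NumPy — im2col convolutions
lowered to BLAS matrix products, hand-written backpropagation (verified
against central finite differences in float64 in the test suite), and a
seed-fixed shuffle stream — so training is bit-reproducible on any
machine.  Masks are binarized {0,1}; predictions threshold the sigmoid at
0.5 (an unbiased default; the cut is exposed).

Evaluation uses per-class confusion counts: precision = TP/(TP+FP),
recall = TP/(TP+FN), IoU = TP/(TP+FP+FN).  With binary labels there is
k = 1 foreground category, and both the mean pixel accuracy (mPA) and the
mean IoU (mIoU) average over the k+1 = 2 classes including background;
"segmentation accuracy" is overall pixel accuracy (TP+TN)/total.

## Morphometry details

* **Point order.** Foreground voxels are enumerated in lexicographic
  (z, y, x) order.  DBSCAN cluster identity follows first appearance in
  that order, which makes the whole trait table deterministic.
* **Core rule.** A point is a core point when its eps-ball contains at
  least `min_points` points *including itself* (the scikit-learn
  convention); border points join the earliest cluster that reaches them.
  Defaults: eps 4 voxels, min_points 10, min_cluster_voxels 50.
* **Contour shell.** The input to surface reconstruction is the set of
  grain voxels with at least one 6-connected background neighbour (volume
  borders count as background).  Grains are already isolated by
  clustering, so no marker-based splitting is needed before contour
  extraction.
* **Alpha shape.** The shell points are Delaunay-tetrahedralized;
  tetrahedra with circumradius < alpha (default 12 voxels) are kept, and
  the boundary is the set of triangles belonging to exactly one kept
  tetrahedron.  Degenerate (near-zero-volume) tetrahedra — exactly
  co-planar lattice points — are always kept so they cannot punch holes in
  the mesh.  For convex clouds and alpha at least the cloud diameter the
  result equals the convex hull (checked against `scipy` hulls in tests).
  Alpha must exceed the grain's smallest semi-axis in voxels, otherwise
  the hollow shell grows a spurious inner surface; 12 exceeds the default
  phantom semi-axis c (≤ 11 voxels, and ≤ 5.5 for the small UNet-facing
  phantoms).
* **Oriented bounding box.** Box axes are the eigenvectors of the point
  covariance (principal axes), not a minimum-volume search — deterministic,
  fast, and exact for ellipsoids.  The extent along each axis is
  (max − min projection + 1) voxels, scaled by P/1000 to mm.  The +1
  accounts for the unit width of the voxels whose centers the points are,
  and makes axis-aligned solid boxes measure exactly their voxel spans.
* **Spike axis and ordering.** The spike axis is the principal eigenvector
  of the full grain cloud, oriented so its z-component is positive
  ("bottom" = the low-z end, where the holder grips the spike base; a
  config flag flips it).  Grains order by ascending centroid projection,
  ties broken by (y, x) lexicographic centroid order.  Spike length is the
  longest oriented-box extent of the full grain cloud; awns or stalk
  fragments do not contribute because segmentation and debris filtering
  remove them.

## The phantom generator

Real validation requires physical spikes; the generator replaces them with
synthetic scans whose ground truth is analytic.  A phantom is a vertical
rachis cylinder with ellipsoidal grains attached in alternating rows
(two-row: two opposite azimuths; six-row: six azimuths 60° apart), a
bright holder annulus on every slice, optional thin awn-like impurity
segments, and i.i.d. Gaussian noise clipped to [0, 255].  A voxel belongs
to a shape iff its center satisfies the analytic inequality — no
partial-volume weighting — so a brute-force per-voxel sweep is an exact
oracle for the rendered voxel set.

Default conditions: 16 grains, semi-axes a ∈ [15, 18], b ∈ [11, 12.5],
c ∈ [10, 11] voxels with the long axis radial and tilted up to 12° out of
the slice plane, 16-voxel axial spacing, 96×96 slices, P = 85 µm,
noise σ = 8 gray levels, intensities background 30 / rachis 120 /
grain 200 / holder 255 / impurity 170.  The spacing guarantees more than
9 voxels of clearance between grain surfaces, which exceeds the top of the
eps working range (7 + 2), so density-clustering ground truth is
unambiguous; reducing the spacing is the intended stress test for touching
grains, for which no recovery guarantee is made.  Grain sizes were chosen
so that the two discretization effects that bound recovery accuracy —
voxel-center rasterization (volume) and the +1-voxel box convention
(extents) — stay below 3% and 5% respectively; at P = 85 µm the phantom
grains are smaller than field barley, which only rescales reported units.
An optional `size_profile="mid-peaked"` scales grain size by position,
emulating the real-spike pattern of largest grains mid-spike.

What the phantom does *not* emulate: partial-volume shading at grain
boundaries, beam hardening, ring artifacts, internal grain structure
(embryo/endosperm contrast), or awn-attached geometry.  Passing phantom
tests therefore demonstrates correctness of the geometry, clustering and
bookkeeping, and the trainability of the network on intensity-separable
tissue — not segmentation performance on real scanner artifacts.

UNet-facing phantoms are generated at 64×64 slices (smaller grains,
a ∈ [8, 10]) so that scaled-down training runs — 200 slices, 10 epochs,
depth 4, base 16 — finish in minutes on one CPU; these are the problem
sizes used by the test suite and the acceptance script.

## Numerical choices and degenerate inputs

* Otsu threshold: exhaustive, vectorized between-class-variance
  maximization over the 256-bin histogram; ties take the lowest cut;
  constant in-mask images are flagged degenerate (assisted segmentation
  then returns the predicted mask unchanged).
* Ellipsoid surface truth: Gauss–Legendre product quadrature (order 96) of
  the parametric surface integral, cross-checked in tests against a dense
  triangulated mesh and, for spheres, the closed form.
* Clustering conservation: cluster sizes plus debris always sum to the
  cloud size (tested).
* Degenerate geometry: fewer than 4 non-coplanar points is an error for
  surface reconstruction; a single point is an error for the bounding box;
  an empty foreground is an error ("no spike detected").

## Known limitations

* Training on CPU limits practical input sizes; the 512×512 default of
  the full protocol is supported but slow in this NumPy implementation.
* Alpha-shape area over a 1-voxel-thick shell underestimates strongly
  curved surfaces by 1–3% (observed on rasterized spheres), which is the
  dominant error term in surface totals.
* DBSCAN cannot split grains that actually touch; the touching-grain
  regime is exposed as a stress mode without a recovery guarantee.
* Group comparison treats spikes as replicates; with few spikes per
  accession the t-tests are anti-conservative for accession-level claims.
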