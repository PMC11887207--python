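# Methods

## Overview

`coroseg` segments the contrast-filled lumen of coronary arteries from CT
angiography (CTCA), given the image volume and a branch-structured centerline
of the vessel tree. The method is unsupervised: it derives one local
segmentation threshold per centerline point from a clustering analysis of a
small vessel-centred image patch, then reconstructs a 3D binary mask from
those thresholds. Everything is driven by Hounsfield Units (HU), the
calibrated CT attenuation scale on which contrast-filled lumen sits at
roughly 300–500 HU, soft tissue near 0–100 HU and calcified plaque above
600–700 HU.

## Pipeline

1. **Resampling.** The volume is resampled to an isotropic 0.25 mm grid
   (trilinear interpolation); the centerline is arclength-resampled so
   consecutive nodes are at most 0.25 mm apart, guaranteeing that no grid
   slice between two nodes is skipped.
2. **Patch extraction.** At every centerline point a 32×32-pixel HU patch is
   sampled at 0.25 mm/pixel (an 8×8 mm field of view) centred on the point.
   The perpendicular (`perp`) variant samples the plane normal to the local
   tangent; the `3axis` variant samples the axial, sagittal and coronal grid
   planes independently. In-plane frames for `perp` are propagated by
   parallel transport along the branch so patch orientation never flips.
3. **Clipping.** Patch intensities are clamped to [100, 600] HU, the
   aorta-derived band that brackets lumen attenuation. This stops the
   clustering from spending clusters on irrelevant extremes (air, bone,
   dense calcium).
4. **Ward clustering.** The patch is partitioned into 7 clusters by
   agglomerative clustering under Ward's minimum-variance criterion, with
   merges restricted to 4-adjacent pixel clusters. The feature is the
   clipped HU value alone; spatial coherence comes from the connectivity
   constraint, so every cluster is a connected image region.
5. **Cluster graph and background removal.** Each cluster becomes a node at
   coordinates (distance in pixels from the cluster centroid to the patch
   centre, cluster mean HU); clusters sharing 4-adjacent pixels are linked,
   with edge weight the Euclidean distance between the embedded nodes. The
   graph is reduced to a minimum spanning tree by Borůvka's algorithm. The
   *vessel path* starts at the cluster under the patch centre and walks MST
   neighbours in non-increasing mean HU until brightness falls below 100 HU;
   every off-path cluster is flattened to the background (lowest-mean)
   cluster's value. This is what detaches touching bright structures —
   the kissing-vessel artifact — provided an intermediate-brightness band
   separates them in the patch.
6. **Second pass and threshold rule.** The cleaned patch is re-clustered
   (same cluster count) and the path re-traced. Path clusters with mean HU
   in (100, 600] are kept; if more than three remain the third one's mean
   becomes the threshold (two interior brightness levels are skipped,
   landing near the lumen edge), otherwise the last one's; if none remain a
   150 HU fallback is emitted and flagged.
7. **Mask painting.** `perp`: every voxel within a 2 mm sphere of the point
   is assigned 1 where HU ≥ threshold and 0 otherwise; points are processed
   in ascending threshold order so narrower (higher-threshold) regions
   overwrite wider ones, and for the first 2 mm after a bifurcation the
   sphere is clipped to the child branch's forward half-space. `3axis`: a
   flat 4 mm disc brush assigns the single grid slice through the point per
   plane (same ordering per plane); the three plane masks are combined by
   voxelwise union. Both variants end with a 1 mm binary median (majority)
   smoothing with a cubic kernel.

## Parameters

| name | default | unit | meaning |
|---|---|---|---|
| `resample_mm` | 0.25 | mm | isotropic working resolution |
| `centerline_step_mm` | 0.25 | mm | max distance between centerline nodes |
| `patch_size` | 32 | px | patch edge (8 mm at 0.25 mm/px) |
| `hu_low`, `hu_high` | 100, 600 | HU | clip band and threshold filter band |
| `n_clusters` | 7 | – | Ward cluster count, both passes |
| `stop_hu` | 100 | HU | vessel-path stopping brightness |
| `fallback_hu` | 150 | HU | threshold when no path cluster is in band |
| `sphere_radius_mm` | 2.0 | mm | perp painting radius |
| `brush_radius_mm` | 4.0 | mm | 3axis per-plane brush radius |
| `smooth_mm` | 1.0 | mm | median kernel edge |
| `forward_only_mm` | 2.0 | mm | forward-half-space extent after a bifurcation |

The defaults are the method's published operating point and are not tuned
per patient. `forward_only_mm` operationalises the rule that painting after
a bifurcation proceeds only in the flow direction; its extent is a
configurable choice.

## Numerical and design choices

* **Coordinate contract.** Voxel arrays are indexed (x, y, z); world
  position = origin + index·spacing; all geometry is computed in world mm.
  Only axis-aligned volumes are accepted.
* **Interpolation.** Trilinear for HU (resampling and patch sampling),
  nearest-neighbour semantics for masks (masks are painted, never
  interpolated).
* **Centerline resampling** subdivides each segment separately, so original
  vertices are retained and total arclength is preserved exactly.
* **Ward determinism.** Cluster labels are canonicalised by first
  appearance in raster order; with a deterministic tie-break the whole
  pipeline is reproducible bit-for-bit. The implementation is backed by
  scikit-learn's connectivity-constrained Ward linkage and is verified
  against an independent brute-force greedy agglomeration oracle.
* **Mixed units in edge weights.** The graph embedding mixes pixels (x) and
  HU (y) without normalisation; HU differences dominate edge weights by
  design — brightness similarity, not geometric proximity, decides which
  clusters the MST keeps close.
* **Threshold band bounds.** The in-band filter is exclusive at 100 HU:
  a cluster mean exactly at the clip floor can only arise from saturated
  background pixels, and counting it in band would make the 150 HU fallback
  unreachable.
* **Degenerate patches.** A constant (or fully sub-band) patch produces an
  empty vessel path, skips background removal, and emits the flagged
  fallback threshold; it never aborts the run. Points whose 8 mm field of
  view leaves the volume are skipped with a warning.
* **Empty-mask metrics.** Overlap metrics are 1 when both masks are empty
  in the ROI and 0 when exactly one is; Hausdorff is the exact symmetric
  maximum, and the mean surface distance averages the two directed means.

## The phantom generator

Clinical CTCA data cannot be redistributed, so the test bench generates
digital phantoms with analytic ground truth: tubes of configurable radius
profile (lumen 400 HU) in a 30 HU background with myocardium (100 HU) and
fat (−100 HU) inclusions, optional calcium blobs (900 HU, excluded from the
lumen truth), smooth cosine-notch stenoses, bifurcating child branches, and
parallel touching twin tubes for the kissing-vessel artifact. Additive
Gaussian noise (σ = 20 HU by default) is applied last; the truth mask is
exact voxel-centre membership and independent of the noise. Tube axes are
deliberately placed off voxel centres, since clinical centerlines never
align with the scanner grid and grid-aligned axes would remove all
partial-volume structure from the patches.

The default study phantom is a 15 mm tube of radius 1.5 mm in an
18×16×24 mm volume at 0.25 mm — small enough that a full two-method run
takes seconds on one CPU while still exercising every pipeline stage.

**What the phantom does not emulate.** Voxels are assigned binarily from
geometric membership: there is no scanner point-spread function, no
beam-hardening, no motion, and no partial-volume averaging at the source
(partial volume appears only through patch interpolation). Two consequences
matter for interpreting results. First, thresholding a near-binary image is
easy, so phantom Dice scores (≈0.91–0.96) overstate what the method achieves
on clinical data. Second, two equal-brightness tubes in exact tangential
contact rasterise with directly adjacent lumen voxels and no intensity dip
between them; intensity-driven clustering then merges both lumens into a
single cluster and background removal cannot detach the twin. On real CT
the scanner PSF provides the dip that makes kissing-vessel separation work;
in the phantom the separation mechanism engages only when an
intermediate-brightness band separates the structures (demonstrated in the
unit tests). The geometric leak of the painted mask into the twin remains
small (<10% of the twin's exclusive volume) regardless, because the 2 mm
painting sphere can only reach a thin crescent of the neighbour.

## Known limitations

* Centerline quality matters: the perpendicular variant inherits any
  roughness of the tangent field through its frames.
* The fixed 7-cluster count and the third-cluster rule are global settings;
  unusual lumen attenuation (poor contrast timing) will shift thresholds.
* Per-plane thresholds in the 3axis variant are selected independently and
  never reconciled before painting.
* Surface metrics use boundary voxel centres, not sub-voxel surfaces.
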