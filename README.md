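# coroseg

Unsupervised coronary artery lumen segmentation from CT angiography (CTCA),
driven by vessel centerlines and Ward clustering — no training data, no
learned weights, and every decision inspectable in Hounsfield Units.

## What it does

Given a CT volume (NIfTI/NRRD, values in HU) and a vessel centerline
(CSV/JSON polylines in world mm), the pipeline:

1. resamples image and centerline to an isotropic 0.25 mm working grid;
2. extracts a 32×32 HU patch (8×8 mm) centred on every centerline point —
   either the true cross-section (`perp`) or the three anatomical planes
   (`3axis`);
3. clips intensities to [100, 600] HU and partitions the patch into 7
   spatially connected clusters by connectivity-constrained Ward linkage;
4. embeds clusters in a graph (x = centroid distance to the patch centre in
   pixels, y = mean HU; edges between pixel-adjacent clusters, weighted by
   Euclidean distance in that embedding), reduces it to a minimum spanning
   tree with Borůvka's algorithm, and walks the *vessel path* — clusters in
   non-increasing mean HU from the centre outward, stopping below 100 HU;
5. flattens all off-path clusters to the background cluster's value
   (removing kissing vessels and other bright neighbours), re-clusters, and
   reads a per-point threshold off the new path: the third in-band
   (100, 600] HU cluster mean if more than three are in band, else the
   last, else a flagged 150 HU fallback;
6. paints a 3D binary mask — thresholding inside 2 mm spheres (`perp`,
   ascending threshold order so narrow lumens overwrite wide ones) or 4 mm
   per-plane brushes combined by union (`3axis`) — and median-smooths it
   with a 1 mm kernel.

Evaluation metrics (Dice = 2TP/(2TP+FP+FN), IoU, precision, recall,
Hausdorff and mean surface distance, lesion-cube ROIs) and a synthetic
phantom generator with analytic ground truth are included. See
`docs/methods.md` for the full model description.

## Worked example

```bash
coroseg simulate --preset tube --out demo --seed 3
coroseg segment --volume demo/volume.nii.gz --centerline demo/centerline.csv \
                --out demo/pred.nii.gz --method perp
coroseg evaluate --pred demo/pred.nii.gz --truth demo/truth.nii.gz \
                 --out demo/report.csv
```

The `simulate` step writes a digital phantom: a straight contrast-filled
tube (radius 1.5 mm, 400 HU) in soft tissue (30 HU) with 20 HU Gaussian
noise, its analytic truth mask, and its centerline. The `segment` step logs

```
INFO coroseg: wrote demo/pred.nii.gz (7210 voxels, 61 thresholds, 0 fallbacks)
```

meaning 61 centerline points each produced a cluster-derived threshold (none
fell back to 150 HU) and the painted, smoothed mask contains 7210 voxels.
The report then reads

```
roi,dice,iou,precision,recall,tp,fp,tn,fn,hausdorff_mm,msd_mm
global,0.9569,0.9173,1.0,0.9173,7210,0,434508,650,0.25,0.0648
```

— the mask agrees with the analytic truth at Dice 0.957, never leaks
outside the true lumen (precision 1.0), and its surface stays within one
voxel (0.25 mm) of the true surface. The same phantom with `--method 3axis`
lands near Dice 0.91. The remaining false negatives sit in the
partial-volume shell at the lumen boundary.

The same API is available from Python:

```python
from coroseg import phantom, segment_vessel_tree, evaluate_masks

vol, truth, cl = phantom.make_phantom(phantom.preset_stenosis(seed=1))
mask, records = segment_vessel_tree(vol, cl, method="perp")
print(evaluate_masks(mask, truth, surfaces=False)["dice"])
```

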