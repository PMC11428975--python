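# tspr — two-step progressive head registration and ROI localization

`tspr` aligns a labelled head atlas to a clinical CT or MRI head volume
and carries the atlas's anatomical labels across, so that a region of
interest (an organ or lesion) can be localized on the clinical slices
without any manual segmentation.  It is aimed at workflows where a
fully annotated reference head (an atlas with per-voxel structure
labels) must be mapped onto heterogeneous, often imperfect clinical
series — thick slices, partial scan coverage, missing teeth, bone
defects — on an ordinary computer, in seconds.

## The method

Head and face are treated as a rigid structure; the whole alignment is a
single 3D similarity transform (rotation `R`, uniform scale `s`,
translation `T`) estimated from the *exterior surface* of the head,
which both CT and MR delineate sharply against air:

1. **Exterior contour extraction.**  Each axial slice is binarized at a
   body/air threshold (−300 HU for CT, Otsu's method otherwise), interior
   regions are filled, clutter is removed with a binary opening, and the
   body mask minus its erosion leaves a one-pixel exterior ring.  Stacked
   in physical coordinates the rings form the head-surface point cloud.

2. **Step one — spatial orientation (rigid).**  The surface is projected
   along the anterior–posterior axis into a face-on depth map.  A
   rectangle over the "eye–nose triangle" is sampled on a uniform 4×7
   grid (28 feature points) in both clouds; the node-paired closed-form
   rigid fit initializes a rigid iterative-closest-point (ICP)
   registration of the two face patches, giving `M1`.

3. **Step two — spatial scale (similarity).**  An axial band of the
   surface around the eye–nose region (the "circular contour") is pushed
   through `M1` and registered to the subject's band with similarity
   ICP (closed-form Umeyama fit per iteration), giving `M2`; the step
   may repeat progressively.  The final transform is the composition

   `M = M2_n · … · M2_1 · M1`   (column-vector convention),

   a 4×4 homogeneous matrix with last row `[0, 0, 0, 1]`.

4. **ROI mapping and evaluation.**  Atlas labels are pulled into the
   subject grid through `M⁻¹` (nearest-neighbour), and localization is
   scored per axial slice `i` by the recall

   `Recallᵢ = |ROI_mapped,i ∩ ROI_ref,i| / |ROI_ref,i|`,

   summarized by max/min/median/mean and the 95% confidence interval
   `mean ± 1.96·s/√n`.

Splitting orientation from scale is what defeats the classic ICP failure
on whole-head surfaces, where a single-stage registration happily locks
the nose onto an ear or matches the face back-to-front (a local
extremum of the ICP objective).

A deterministic synthetic head phantom (ellipsoid cranium, protruding
nose, eye-socket depressions, embedded ROI structures) with exactly
known atlas→subject transforms makes the entire pipeline testable
without clinical data.

## Worked example

```python
import tspr
from tspr.phantom import PhantomSpec, generate_atlas, derive_subject

atlas, labels = generate_atlas(PhantomSpec())
subject, subject_labels, truth = derive_subject(
    atlas, labels, scale=0.93, rotation_deg=(0, 0, 10), translation=(20, 5, 0),
    out_shape=(128, 160, 160), out_origin=(-16.0, -16.0, -16.0),
)

params = tspr.ContourParams(threshold=50.0)
atlas_cloud = tspr.surface_from_volume(atlas, params)
subject_cloud = tspr.surface_from_volume(subject, params)

model = tspr.TSPRRegistration.from_surfaces(atlas_cloud, subject_cloud)
result = model.fit(n_scale_steps=1)
print(result.summary().to_string(index=False, float_format=lambda x: f"{x:.4f}"))
```

```
                step  iterations  rms_mm  converged  scale  rotation_deg  |t|_mm
 orientation (rigid)          23  0.8494       True 1.0000       10.1774 31.7466
scale 1 (similarity)          23  0.5366       True 0.9291        1.0636  7.5323
```

The orientation step recovers the 10° yaw (rigid, scale fixed at 1);
the scale step measures the head-size ratio 0.9291 against the true
0.93 and tightens the band alignment to 0.54 mm RMS — about half a
voxel.  Mapping a labelled structure through the fitted transform and
scoring it against the subject's own labels:

```python
mask = tspr.map_roi(labels, ["optic_nerve_right"], result.final, subject)
series = tspr.recall_per_slice(mask.grid, subject_labels.labels == 2)
print(tspr.summarize_recall(series))
```

```
RecallSummary(max=0.9896907216494846, min=0.9821428571428571,
              median=0.9896907216494846, mean=0.9866715758468336, n=5,
              ci95=(0.983047846175809, 0.9902953055178583))
```

i.e. the automatically mapped optic nerve covers ~99% of the reference
ROI on every slice.  (Structures only one or two voxels wide on their
end slices can still score 0 there — nearest-neighbour mapping at a
sub-voxel offset misses a one-voxel target.)  `result.final.m` is the
4×4 transform matrix; `compose(result.m1, result.m2_list)` reproduces
it exactly.

A command-line interface mirrors the library (`tspr --help`):
`phantom`, `extract-contour`, `sample-features`, `select-band`,
`register`, `map-roi`, `evaluate`.

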