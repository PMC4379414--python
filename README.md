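# wristseg

Automated segmentation of the 15 wrist bones — distal radius and ulna, the
eight carpals, and the five metacarpal bases — in low-field (0.2 T)
T1-weighted MR volumes.

Low-field extremity scanners are cheap and patient-friendly but offer no
fat-suppressed sequences: skin and bone marrow share one intensity band, so
single-object thresholding or edge tracking fails.  `wristseg` instead
segments all bones simultaneously with a *watershed from markers*: for every
bone a small seed region guaranteed to lie inside it is constructed
automatically, a background marker is placed in the surrounding soft tissue,
and the gradient-magnitude relief is flooded from all markers at once, so
every boundary is decided by competition between neighbouring basins rather
than by an absolute threshold.

Markers come from a three-stage atlas-based procedure:

1. **Distal ulna/radius** — a representative axial slice is selected from the
   mean-intensity axial profile (the first proximal maximum with a
   sufficiently deep, nearby minimum marking the wrist joint), a 2D atlas
   slice is registered to it (rigid → affine → coarse and fine free-form
   stages, mean-squares metric), the two propagated markers are extended into
   3D paths by best-first region growing over 10 slices.
2. **Metacarpal bases** — the slice is selected by thresholding at the
   maximum-entropy level + 200 gray values and filtering clusters by axial
   extent and distal position; five registered markers are reduced to their
   central pixels and grown distally.
3. **Carpals** — a 3D carpal region is built between the envelopes of the two
   previous segmentations and two lateral support planes; a 3D atlas of the
   region is registered to it and eight volume markers are propagated,
   thresholded at 240/255, intensity-filtered, and capped at the eight
   largest components.

After each watershed the basins (bone marrow) are dilated by one unit diamond
to recover the dark cortical shell.  Segmentations are scored against ground
truth with the three-point ROC area

AUC = FPR·TPR/2 + (1 − FPR)(1 + TPR)/2,

the Jaccard mean similarity MS = |Im_g ∩ Im_s| / |Im_g ∪ Im_s|, and the
granulometric mean absolute distance

MAD = Σₙ n·PS(n) / Σₙ PS(n),

where PS is the pattern spectrum of the XOR of the two masks under
successive unit-diamond openings — an estimate of the boundary offset in
voxels.

Because no public low-field wrist data exist, the package ships a synthetic
wrist **phantom** generator (`wristseg.phantom`): seeded, smoothly deformed
volumes with a dark background, bright-skinned soft tissue, and 15 bone
bodies (bright marrow in thin dark cortical shells) plus exact ground-truth
labels and derived atlas bundles.  It reproduces the intensity structure the
algorithm depends on, not anatomical shape detail.

## Worked example

```python
import numpy as np
from wristseg import PhantomSpec, PipelineConfig, evaluate, generate_phantom, run
from wristseg.phantom import corpus_atlas

spec = PhantomSpec(shape=(96, 96, 72), seed=3)
volume, truth = generate_phantom(spec)          # synthetic wrist + ground truth
atlas = corpus_atlas()                          # atlas derived from another phantom

result = run(volume, atlas, PipelineConfig(), spacing=spec.spacing)
report = evaluate(truth, result.labels)
print(report.aggregates.round(3))
```

prints

```
             auc_mean  auc_std  ms_mean  ms_std  mad_mean  mad_std   n
carpals         0.940    0.021    0.881   0.043       1.0      0.0   8
metacarpals     0.932    0.005    0.865   0.010       1.0      0.0   5
radius_ulna     0.950    0.009    0.900   0.018       1.0      0.0   2
overall         0.939    0.017    0.878   0.034       1.0      0.0  15
```

All 15 bones are recovered; MAD of exactly one voxel says the automated
boundaries sit one voxel inside/outside the true ones on average (the
watershed traces the inner cortical surface and the unit dilation compensates
most, not all, of the shell), and MS around 0.88 is the corresponding volume
overlap at this grid scale.

The same pipeline is available from the shell:

```bash
wristseg phantom --seed 3 --out case/ --atlas-seed 100 --shape 96 96 72
wristseg run --volume case/volume.nii.gz --atlas case/atlas --out seg/
wristseg evaluate --ground-truth case/labels.nii.gz --segmentation seg/segmentation.nii.gz
```

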