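# vessel4d

Voxel-wise segmentation of the cerebral vasculature in dynamic (4D) CT.

A 4D CT acquisition images the passage of contrast agent through the brain
as a time series of volumes. Vessels are the only structures whose
attenuation changes substantially over time, and `vessel4d` exploits
exactly that: it collapses the time axis into exposure-weighted temporal
statistics, classifies candidate voxels with a random forest over local
image features, and cleans the result morphologically. The package is
aimed at researchers working on stroke imaging pipelines (occlusion and
collateral assessment, arterial input function selection) and, more
generally, at anyone who needs a reproducible, fully tested
temporal-feature segmentation baseline with a ground-truth phantom.

## Method

With per-time-point exposures `E_i` and weights `w_i = E_i / Σ_j E_j`, the
weighted temporal average and variance of the intensity `I_i` are

```
WTA = Σ_i w_i · I_i          WTV = sqrt( Σ_i w_i · (WTA − I_i)² )
```

The pipeline is:

1. **Candidates** — voxels with `WTV > μ + 1.5σ` of the WTV distribution;
2. **Classification** — a random forest (100 trees, depth ≤ 30) over 24
   features per candidate voxel: WTA, WTV, the first (pre-contrast) time
   point, the signed distance to the intracranial cavity border, local WTV
   histogram parameters (mean, std, mode, entropy) in 5³ and 9³
   neighbourhoods, and Hessian eigenvalues of the WTV at 0.5–2.0 mm
   scales;
3. **Postprocessing** — removal of 26-connected components smaller than
   25 voxels (2.3 µL at 0.43 × 0.43 × 0.5 mm voxels), then ≤ 10 iterations
   of 3×3×3 majority-voting hole filling.

Training samples 10% of the annotated vessel voxels plus an equal-count
background sample from the annotation subvolumes. Evaluation implements
DSC, Hausdorff distance (plus 95th-percentile and modified variants),
contour mean distance, absolute volume difference and voxel-wise confusion
statistics with optional 1-voxel boundary-band exclusion.

Because clinical 4D CT cannot ship with a package, `vessel4d` includes a
parametric 4D vascular phantom — tubular vessels with gamma-variate
enhancement curves inside a cavity/skull geometry, with
`1/sqrt(exposure)`-scaled noise — that provides exact ground truth for
training, evaluation and the test suite. See `docs/methods.md` for the
full model description and design decisions.

## Worked example

Train on three phantom cases, segment a held-out fourth, and evaluate
against its ground truth:

```python
import vessel4d as v
from vessel4d.model import VesselSegmentationModel

cases = [v.generate_phantom(v.default_phantom_spec(variant=i), seed=101 + i)
         for i in range(3)]
held_out = v.generate_phantom(v.default_phantom_spec(variant=3), seed=104)

results = VesselSegmentationModel(cases).fit(seed=7)
print(results.summary())

seg = results.segment(held_out.volume, held_out.cavity)
report = v.evaluate(seg, held_out.truth, exclude_boundary=False)
for key, val in report.to_dict().items():
    print(f"{key:>12}: {val:.4f}")
```

Output:

```
Vessel segmentation model (random forest)
=========================================================
Training cases:        3
Training samples:      2820 (1410 vessel / 1410 background)
Positive fraction:     0.10 of annotated voxels
Features:              24
Forest:                100 trees, max depth 30
Seed:                  7

Leave-one-out cross-validation
---------------------------------------------------------
fold     case      n      AUC  Youden thr     acc
   0    case0   1010   1.0000       0.760  0.9980
   1    case1    904   1.0000       0.780  0.9967
   2    case2    906   0.9997       0.730  0.9923
Mean AUC: 0.9999

Top features by importance
---------------------------------------------------------
  hessian_0.5mm_l3       0.2048
  wtv                    0.1775
  wta                    0.1723
  ...

         dsc: 0.9746
       hd_mm: 1.2900
      mhd_mm: 0.0459
     hd95_mm: 0.4300
      cmd_mm: 0.0456
 avd_percent: 4.9474
 sensitivity: 0.9987
 specificity: 0.9985
    accuracy: 0.9985
```

The cross-validation table shows each phantom case held out in turn: the
24-feature forest separates vessel from background almost perfectly (AUC
≈ 1) on these study conditions. On the held-out case, a Dice coefficient
of 0.97 means segmentation and truth overlap almost completely; the
modified Hausdorff distance of 0.046 mm — an order of magnitude below the
0.43 mm in-plane voxel size — means the recovered surface sits within a
fraction of a voxel of the true lumen almost everywhere, while the 1.29 mm
(worst-case) Hausdorff distance reflects a handful of partial-volume rim
voxels.

The same workflow is scriptable from a shell via the `vessel4d` CLI
(`phantom`, `features`, `train`, `segment`, `evaluate` subcommands); every
run writes a manifest sufficient to reproduce it bit-identically.

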