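# Methods

## Problem and approach

Segmenting the cerebral vasculature in dynamic (4D) CT is hard for
tracking- and contour-based methods: intensity varies strongly along a
vessel (from 500+ HU in the proximal arteries down to the 20–40 HU of
surrounding parenchyma at partial-volume boundaries), and pathology or
foreign objects interrupt vessel continuity. This package instead treats
segmentation as voxel-wise pattern recognition over features that exploit
the one thing unique to vessels in a dynamic acquisition: attenuation
*changes over time* where contrast agent passes.

The pipeline has three stages:

1. **Candidate selection.** The weighted temporal variance (WTV) image is
   thresholded at `mu + 1.5 sigma` of its own intensity distribution
   (strict `>`; `mu`, `sigma` from the raw voxel values, not a binned
   histogram). This removes voxels with no temporal contrast variation and
   shrinks the classification workload without discarding vessel voxels.
2. **Random-forest classification** of the candidate voxels on a
   24-feature vector (below); 100 trees, maximum depth 30. The candidate
   gate is absolute: non-candidates get probability exactly 0.
3. **Postprocessing.** 26-connected components smaller than 25 voxels are
   discarded (strictly smaller: a 25-voxel component survives; at
   0.43 × 0.43 × 0.5 mm voxels the cut-off corresponds to 2.3 µL), then
   iterative 3×3×3 hole filling runs for at most 10 passes to close
   under-segmented cores of large, fast-flowing vessels.

## Temporal weighting

Acquisition exposures differ per time point, and quantum noise scales as
`1/sqrt(exposure)`. With weights `w_i = E_i / sum_j E_j`:

    WTA = sum_i w_i * I_i
    WTV = sqrt( sum_i w_i * (WTA - I_i)^2 )

The default protocol is 19 time points at 1×200, 13×100 and 5×75 mAs
(weight 200/1875 ≈ 0.1067 for the first point), with acquisition times
5 s, then every 2 s to 31 s, then every 5 s to 56 s.

## The 24 features

Per candidate voxel, in fixed column order: WTA, WTV, T0 (the first,
minimal-contrast time point), signed Euclidean distance to the
intracranial-cavity border, four local-histogram parameters (mean,
standard deviation, mode, entropy) of the WTV in 5×5×5 and 9×9×9
neighbourhoods, and three Hessian eigenvalues of the WTV at scales 0.5,
1.0, 1.5, 2.0 mm.

Numerical choices where the design was open:

* **Histogram binning**: 32 bins spanning each neighbourhood's own
  `[min, max]` range. Local-range binning compares a vessel to its
  immediate surroundings and is invariant to global intensity offsets; the
  bin count is configurable. A flat neighbourhood degenerates to one
  occupied bin.
* **Entropy**: `E = -sum_i p_i log2(p_i + eps)` with `eps = 1e-4` added
  inside the logarithm, exactly as the formula is stated. The flat
  neighbourhood therefore yields `-log2(1 + eps) ≈ -1.44e-4`, slightly
  below zero — intentional, not clipped.
* **Mean/std** come from the raw neighbourhood values, not the binned
  representation: bin-free moments are exact and only mode/entropy need
  bins. **Mode** is the centre of the most populated bin; ties break to
  the lowest bin for determinism.
* **Border handling**: replicate-edge padding, so feature maps never
  shrink.
* **Hessian**: Gaussian derivatives with per-axis sigma in voxels
  (`sigma_mm / spacing`, anisotropy-aware), second derivatives taken with
  respect to physical mm and gamma-normalised with exponent 1 (multiplied
  by `sigma_mm^2`); filter truncation at 6 sigma keeps the derivative
  kernels' residual negligible on flat regions. Eigenvalues are sorted by
  ascending absolute value, the convention of tubular-structure filters: a
  bright tube shows `|l1| ≈ 0` and `l2 ≈ l3 < 0`.
* **Cavity distance**: border voxels (foreground with a background
  6-neighbour) are at distance 0; negative inside, positive outside, in
  physical mm. A graded distance rather than a binary inside/outside flag
  keeps the extracranial carotids and jugulars reachable by the
  classifier.
* **Hole filling**: the kernel size and iteration count alone do not fix
  an algorithm, so the filler is iterative binary majority voting — a
  background voxel flips when at least 14 of its 26 neighbours are
  foreground (`ceil(26/2) + 1`, configurable). Foreground is never
  removed, growth is monotone, and iteration stops early at convergence.

## Training

Positives are a uniform random 10% subset of the annotated vessel voxels;
negatives are an equal-count uniform sample (without replacement) of all
non-annotated voxels inside the annotation subvolumes — not restricted to
candidates, taking the sampling rule literally. One master seed fans out
to per-case sampling and forest training, and is recorded in the model
metadata, so refits are bit-reproducible.

`VesselSegmentationModel.fit()` runs leave-one-out cross-validation across
cases (each held-out case scored by ROC AUC on its own sampled voxels) and
reports a Youden-J-optimal operating point per fold. The default operating
point is probability 0.5: choosing it by visual inspection is not
reproducible, so both the fixed default and the Youden optimiser are
exposed.

## Evaluation measures

DSC, HD, MHD, 95% HD, CMD, AVD and voxel-wise
sensitivity/specificity/accuracy. Conventions:

* Boundary voxels are foreground voxels with at least one background
  6-neighbour (the grid edge counts as background); distances are
  voxel-centre to voxel-centre in mm.
* HD is the maximum of the two directed maxima; MHD the maximum of the two
  directed means (both explicit in the definitions). For HD95 and CMD the
  directionality is not fixed by the definitions, so both use the pooled
  union of the two directed distance sets — the common convention —
  and this choice is configurable in principle via the shared
  `surface_distances` kernel.
* AVD is `|V_seg − V_ref| / V_ref × 100`; reference-normalised, hence
  deliberately asymmetric.
* Confusion statistics can exclude a 1-voxel boundary band
  (`dilate(ref, 3^3) \ ref`) from the evaluation domain. The band contains
  no reference positives, so exclusion can only raise specificity and
  never changes sensitivity; this is asserted by construction in the
  tests.
* Both-empty masks: DSC = 1, distances 0. Empty-vs-nonempty raises rather
  than returning sentinels, because silent sentinels corrupt aggregate
  statistics.
* Across disconnected annotation subvolumes, CMD combines by mean and HD,
  MHD, HD95 by maximum.

## The phantom

The generator defines the study conditions for all experiments and tests:

* grid 64×64×64 voxels at 0.43 × 0.43 × 0.5 mm (the protocol's voxel
  size; the full 512×512×320 clinical grid is supported but not needed at
  desk scale), 19 time points at the default protocol above;
* six tubular vessels (polyline centrelines, radii 0.65–2 mm) spanning
  arterial (delay ≈ 7–9 s, narrow gamma-variate) and venous (delay
  ≈ 13–15 s, broad) enhancement, peak enhancements 230–350 HU, with a
  linear partial-volume ramp across a one-voxel rim around each lumen;
* static soft-tissue background at 30 HU, an ellipsoidal intracranial
  cavity mask, a static ≈1000 HU skull shell just outside it;
* additive Gaussian noise with per-time-point standard deviation
  `6 HU × sqrt(E_max / E_i)` — the simplest model consistent with
  quantum-noise dominance (a Poisson option would be the natural
  refinement);
* five annotation subvolumes (22³ voxels) centred on distinct vessels,
  mimicking a partially annotated reference standard;
* `variant` applies small deterministic jitter (centrelines ~1 mm, radii
  ±10%, delays ±1 s) so a set of variants behaves like distinct cases of
  one population for cross-validation;
* a motion injector translates chosen time points (circularly, so the
  corruption is exactly invertible) to reproduce the characteristic
  failure mode in which unregistered motion elevates the WTV over broad
  static regions.

What the phantom does **not** emulate: anatomically realistic branching
trees, beam hardening and streaks, spectral bone/tissue effects, in-vivo
enhancement-curve shapes, or inter-patient variability beyond the jitter
above. Passing the end-to-end tests therefore shows the pipeline recovers
tubular, temporally enhancing structures from noisy dynamic volumes under
the stated acquisition model — it does not certify clinical accuracy.

## Problem sizes and known limitations

The end-to-end experiment trains on three phantom cases and segments a
held-out fourth on the 64³ × 19 grid; feature extraction touches only the
~3% of voxels passing candidate selection, so a full train-plus-segment
cycle takes well under a minute on one CPU. The random forest is the only
stochastic component; all randomness flows from one seed, and reruns are
bit-identical.

Limitations: the candidate threshold assumes a background-dominated WTV
distribution (a volume that is mostly vessel would shift `mu + 1.5 sigma`
upward); severe unregistered motion inflates the WTV globally and is an
acknowledged failure mode rather than something the pipeline corrects; no
topological guarantees are made about the segmented tree; forest
probabilities are used uncalibrated.
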