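# Methods

## The measurement model

`ctcomp` estimates whole-body composition — bone, lean and fat mass — of a
dog from an axial CT stack. The chain is:

1. **Masking.** Everything outside the animal (the positioning cradle,
   straps) is set to air (−1024 HU), either by per-slice closed polygons or
   by an automatic body mask that keeps the largest 8-connected component
   of pixels at or above the fat threshold (−214 HU). Point-in-polygon
   membership uses the even-odd rule with boundary pixels counted *inside*,
   a deliberately conservative retention of body pixels.
2. **Down-conversion.** The 16-bit HU raster is folded to 8-bit greyscale,
   two HU per greyscale step, with water centred in the 256-value range:
   `HU = 2·GU − 254`. The forward map is `GU = clamp(⌊(HU + 254)/2⌋, 0, 255)`
   — floor-then-clamp is the unique rule that reproduces all six tissue
   range endpoints (fat −214…7 HU ↔ GU 20…130, lean 8…187 ↔ 131…220,
   bone 188…3072 ↔ 221…255), verified by exhaustive scan in the tests.
   The inverse map returns the *lower edge* of each 2-HU bin; a bin-centre
   mode (`2g − 253.5`) exists but is off by default because lower-edge is
   what makes the endpoint equivalences exact.
3. **Partitioning.** Each pixel is classified by inclusive greyscale range
   membership into fat (20–130), lean (131–220), bone (221–255) or
   unclassified (0–19: air, lung, partial volume — no tissue). Per slice
   and tissue the pixel count, area, mean greyscale value and population
   variance are recorded. A histogram-valley helper can *suggest*
   alternative boundaries, but suggestions never silently override the
   configured ranges.
4. **Volume, density, weight.** Tissue volume integrates slice areas with
   the rectangular rule over the **inter-slice spacing** (default 10 mm),
   not the slice thickness (5 mm): with gapped acquisition each slice
   stands for the whole inter-slice interval, so the estimate extrapolates
   to the full body; integrating over the thickness would halve every
   weight. A trapezoidal rule is available by configuration. Density comes
   from the linear calibration `ρ = 1.0062 + 0.00601·HU` (g/cm³) applied
   to the whole-animal, pixel-count-weighted mean greyscale value per
   tissue, converted back to HU; weight is volume × density. The
   CT-derived bodyweight is the sum of the three tissue weights, and the
   lean:fat ratio is the lean/fat weight quotient (reported as missing,
   never infinity, when fat is absent).
5. **Statistics.** Bland-Altman limits of agreement compare CT-derived
   with scale-measured bodyweight: differences are *derived − measured*
   (an underestimating method gives negative means), limits are
   mean ± 1.96·SD (sample SD), and the signed range is lower − upper =
   −3.92·SD. The p-value attached to a Bland-Altman row is a two-sided
   one-sample t-test of the differences against zero — the source data
   report a p per agreement row without naming a test, and this is the
   conventional companion to a mean-difference analysis; it is an assumption
   and is documented as such. Breed differences in lean:fat use an exact
   two-sided Mann-Whitney U test (see below).

## Design choices where the design was open

- **Global vs per-slice density.** The calibration could be applied per
  slice or once per animal. The default is one whole-animal mean per
  tissue, because the final report carries one weight per tissue per
  animal; a per-slice mode (`per_slice_density=True`) is available and
  agrees with the global mode to a few percent on phantoms.
- **8-bit pathway for mean HU.** Mean tissue attenuation is computed from
  the 8-bit data, since that is what the partitioning stage ingests. Two
  consequences: (a) the greyscale quantisation biases means by up to 1 HU
  (each bin reports its lower edge); (b) bone HU saturates — every voxel
  at or above 256 HU maps to greyscale 255, so a bone compartment with a
  true mean of ~425 HU reports a converted mean of ~253 HU. Both effects
  are shared by the ground-truth definition (below), so they cancel in
  self-consistency tests but are real properties of the 8-bit pathway.
- **Calibration slope.** The default slope 0.00601 g/cm³ per HU makes
  adipose tissue (~−100 HU) come out near 0.41 g/cm³, far from the
  physical ~0.92; the alternative slope 0.00106
  (`ALTERNATIVE_DENSITY_SLOPE`) gives ~0.90. The default is kept for
  fidelity to the calibration as published; the slope is a config field
  and every report header names the slope actually used. Under the default
  slope the marginal mass of a voxel below greyscale ~44 is negative (the
  per-tissue weight is not monotone in added low-attenuation voxels), and
  a tissue whose mean falls below about −167 HU would produce a
  non-positive density — this raises an error advising slope review rather
  than returning a negative mass.
- **Exact Mann-Whitney.** U is the first group's rank-sum statistic with
  midranks for ties. The exact two-sided p enumerates all C(n+m, n)
  assignments of the pooled multiset (so ties are handled exactly) and
  doubles the smaller tail, capped at 1. Enumeration is used when both
  groups have ≤ 10 observations (C(20,10) ≈ 1.8×10⁵ assignments,
  instantaneous); beyond that the tie-corrected normal approximation
  without continuity correction is used and logged.
- **Rounding.** Report tables round to 1 decimal, half away from zero;
  all internal computation is unrounded, and group summaries of ratios
  average the unrounded per-animal ratios.

## The phantom generator

No deposited scans exist for this kind of study, so the package ships a
synthetic phantom generator that emulates the acquisition: 5 mm slices at
10 mm centre-to-centre spacing (gapped acquisition), a 480 mm field of
view, and an elliptical body cross-section tapering toward both ends
(half-cosine profile), built from an outer subcutaneous fat rim (default
10 mm), a lean fill, and circular bone rods placed deterministically in
the lean core. An optional cradle crescent of +300 HU sits outside and
below the body to exercise masking. A single seed drives everything
through per-slice child streams, so volumes are bit-identical across
reruns.

Tissue HU values are truncated normals. The default (*classifiable*)
samplers are bounded strictly inside each tissue's classification range —
fat N(−100, 25²) on [−214, 7], lean N(60, 20²) on [8, 187], bone
N(400, 150²) on [188, 1200] — so every voxel is recovered by threshold
partitioning and any disagreement is an algorithm bug, not a modelling
effect. A *realistic* mode widens the bounds across classification
boundaries to exercise misclassification accounting. The generator does
**not** model partial-volume averaging at tissue interfaces, beam
hardening, scatter, noise texture, or canine anatomy; passing phantom
tests therefore demonstrates correctness of the pipeline's arithmetic and
bookkeeping, not segmentation accuracy on real animals.

Ground truth is defined by direct voxel counting: per-tissue counts
(total and per slice), exact volume = count × voxel volume (pixel area ×
inter-slice spacing), and true mean HU. Two weights are recorded: a
*self-consistent* weight that pushes the true voxels through the
pipeline's own greyscale quantisation and density model (the appropriate
target for pipeline-recovery tests, where agreement is exact up to float
error), and an independent *physical* weight from user-specified true
densities (fat 0.92, lean 1.04, bone 1.30 g/cm³) that plays the role of
a scale measurement in end-to-end runs.

Acquisition-gap behaviour is a property, not an accident: with spacing =
thickness (continuous acquisition) recovered volumes equal truth exactly;
with spacing = 2× thickness, a constant cross-section is still exact, and
for tapering bodies the volume error is bounded by (gap width) × (number
of gaps) × (largest area change between adjacent dense slices) — asserted
as a property test against paired dense/gapped phantoms built from the
same analytic taper profile.

## Problem sizes in the tests

Unit and property tests use 12-slice, 64² phantoms. The end-to-end
recovery check runs one 96-slice 256² tapered phantom with cradle and
auto-masking (≈6.3 M voxels) plus a 128² gapped/dense pair; the whole
suite completes in well under a minute on one CPU.

## Known limitations

- Visceral vs subcutaneous fat separation is out of scope.
- The 8-bit pathway compresses bone attenuation (saturation at 256 HU on
  conversion), so bone "mean HU" and hence bone density are systematically
  low relative to 16-bit analysis; bone weights remain internally
  repeatable.
- DICOM support covers single-frame, uncompressed, signed 16-bit series;
  multi-frame and compressed transfer syntaxes are not handled.
- The Bland-Altman p-value test choice (one-sample t) is an assumption,
  as is even-odd boundary-inclusive polygon membership; both are fixed and
  documented rather than configurable guesses.
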