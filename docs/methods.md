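# Methods

This note documents the measurement model, the numerical choices, and
what the synthetic fixtures do and do not establish about real imagery.

## Pipeline model and assumptions

One organism per image. The chain is detect → stage-classify → route →
prompt → segment → post-process → area. Assumptions inherited from the
deployment setting: images are top-down microscopy frames with the
recruit wholly inside the frame; pixel calibration is embedded in image
metadata or supplied explicitly; the detector emits boxes in the frame of
the image it is shown; segmenters emit masks in the frame of the image
they are shown.

**Coordinate convention.** Continuous pixel coordinates, origin top-left,
pixel (0, 0) spanning [0,1)×[0,1). Boxes are stored as continuous corner
values in the original acquisition frame. This makes edge midpoints exact
rationals of the corners and per-axis rescaling associative. Prompts are
constructed in the original frame and affinely rescaled to the
segmentation frame (midpoints map to midpoints under per-axis scaling);
constructing them post-resize would give the same geometry but tie the
prompt set to a model detail rather than to the physical image.

**Frames and resampling.** Detection runs on a square 640-px frame,
segmentation on a square 1024-px frame (defaults, configurable); area is
always computed on the mask mapped back to the original frame so the
metadata pixel size applies unmodified. Frame changes use nearest-
neighbour resampling with integer index arithmetic
(`floor(((2j+1)·s)/(2d))` per axis): this preserves binarity, is bit-
reproducible, and makes the up-then-down round trip through any frame at
least as large as the original an exact identity — the property behind
the exact end-to-end identity test. The residual bias of nearest-
neighbour mapping for frames *smaller* than the original is bounded by
the boundary pixel count and is measured by the disk oracles.

**Stage routing.** The routing label comes from the detector's
classification at inference time; manifest grades are used only for
evaluation stratification. Under the `inverted` ablation configuration an
early detection takes the late branch in full — late segmenter *and*
late (box-only) prompt configuration — and vice versa, mirroring how a
stage-inversion ablation is run against a dual-branch design.

**Post-processing.** Largest 8-connected component intersecting the
detection box; optional hole filling; components below
`min_component_px` (default 16) are discarded as noise. Failures at any
stage (missing calibration, no detection above the confidence floor,
empty mask) produce flagged records, never silent drops; an unreadable
file is an I/O error per image and a flagged row at batch level.

## Evaluation statistics

AR = A_pred/A_true per image; per stratum we report n, AAR, MAR,
mean ± sample (N−1) SD of AR, and the number of excluded (failed)
records. Failed records are excluded from ratio statistics because AAR
is a statement about produced predictions; mixing in detection failures
would conflate two error modes that the flags already separate.

The acceptance band is the closed interval [1−tol, 1+tol], tol = 0.05 by
default. The closed/strict distinction is measure-zero for continuous
ARs; the comparison is implemented float-robustly (an AR sitting exactly
on the printed band edge counts as accepted even when rounding puts
|AR−1| one ulp above the tolerance) and the strict variant is available
via `closed=False`.

Two-arm comparisons always compute ΔAAR = AAR_new − AAR_ref and
Δ(|Bias|) = |MAR_ref−1| − |MAR_new−1|. The two published reporting
conventions (`table6`: reference = baseline, new = final; `table7`:
reference = final, new = ablation) differ only in which arm plays which
role — the formulas are identical once roles are assigned — so the CLI's
`--convention` flag fixes the role assignment and labels the report
rather than switching arithmetic.

Detection precision/recall use greedy one-to-one matching by descending
confidence at box-IoU ≥ 0.5, with vacuous denominators defined as 1.
Mask IoU is defined as 1 for two empty masks and 0 when exactly one is
empty.

## Calibration handling

Precedence: explicit override > JSON sidecar (`<image>.calib.json`,
`{"um_per_px": x}`) > OME-XML PhysicalSizeX/Y > TIFF resolution tags
(unit inch/cm converted to µm/pixel). Missing calibration is an error:
a silently assumed pixel size corrupts every downstream area and
acceptance statistic. Per-axis sizes are averaged only when isotropic to
0.1% relative; beyond that the image is rejected because the area
formula assumes a scalar s. Written TIFFs store pixels-per-centimeter as
the best rational whose numerator and denominator both fit the uint32
RATIONAL fields, giving write/read round-trip errors near 1e-12
relative, comfortably inside the 1e-9 contract.

## Reference backends

No trained networks ship with the package; the detector/segmenter
contracts are the extension points, and three deterministic backends
stand behind them:

* **Mock detector** — ground-truth box plus uniform corner jitter in
  [−j, +j] px, drawn once per (seed, image), clamped to the frame,
  re-drawn up to 100 times if degenerate. Confidence fixed at 0.99.
* **Perturbation segmenter** — ground truth dilated (δ>0) or eroded
  (δ<0) with a discrete disk footprint of radius |round(δ)|, applied in
  the ground-truth frame. This is the controlled-error oracle: on a
  radius-r disk it shifts AR to ≈((r+δ)/r)², emulating the
  over-segmentation (cup leakage, tissue transparency) and
  under-segmentation regimes seen in real recruits. Discrete-disk
  dilation undershoots the Euclidean offset slightly (measured ≈0.8%
  at r=50, δ=2), inside the 1% oracle tolerance.
* **Threshold segmenter** — grayscale Otsu inside the prompt box, veto
  of any connected component containing a background prompt point,
  largest surviving component, minimum-size filter. The veto is a
  deterministic classical analogue of a negative prompt suppressing mask
  expansion; it is not a claim about how a promptable neural segmenter
  treats a negative point on tissue. Note the corollary: with a
  perfectly tight box the edge midpoints can touch tissue and veto the
  true component, so box derivation for this backend pads by 2 px by
  default.

Batch-scale oracle backends receive per-image ground truth through an
optional `bind(image_id)` hook invoked by the pipeline before each
image; the detect/segment contracts themselves stay pure and
image-frame-only.

## Synthetic fixtures

The generator emulates the features the pipeline's logic actually
depends on: a roughly circular tissue region (radius perturbed by
low-order boundary harmonics, orders 2–3, amplitudes 4%/2.5%), a darker
textured corallite ring (12 px), a multiplicative linear illumination
ramp (±7.5%), additive Gaussian noise (SD 0.02 of full scale), and
embedded pixel calibration. The two developmental regimes are encoded as
boundary contrast: early tissue sits 0.12 above the 0.35 background
plate (low contrast), late tissue 0.48 above it — so the early/late
contrast ordering holds for every seed.

Default study conditions: 256×256 px frames at 3.5 µm/px; base tissue
radius 60 px for single fixtures and 30 px for time-series cohorts
(sized so a 0–23-week geometric growth series at 1.05×/week still fits
the frame with its cup ring); ground truth rasterized by the
pixel-center inclusion rule, which is exact, orientation-free, and gives
closed-form disk-area oracles with O(perimeter) discretization error.
Growth is modeled as geometric radius scaling — the simplest monotone
law consistent with a declining multi-week census; no biological growth
curve is claimed. Seeding expands one root seed into per-image seeds via
a stable 32-bit hash of (seed, week, index), so partial regeneration
reproduces identical fixtures.

What the fixtures do **not** emulate: real coral texture, septal
overgrowth, damage, multi-recruit scenes, focus/exposure artifacts, or
the finer A–G pigmentation grades (only the binary contrast regimes are
encoded). Passing tests therefore establish the correctness of the
geometry, calibration, routing, measurement and evaluation machinery
under controlled error — not the segmentation accuracy of any particular
trained model on real imagery.

## Problem sizes and determinism

The test suite and acceptance script run the identity experiment on 50
fixtures, the auto-acceptance recovery experiment on 500 fixtures with a
Bernoulli(p = 0.7) accept/reject draw (accepted images segmented
exactly, rejected ones perturbed ±4 px, far outside the ±5% band for
every radius in the series), and the calibration round-trip on 100
pixel-size values spanning [1e-3, 1e3] µm/px. The expected AAR in the
recovery experiment is exactly 100p, and the empirical value is checked
against a 3-Monte-Carlo-SE band (±6.1 points at n = 500). All randomness
flows from explicit seeds; batch re-runs produce byte-identical CSVs.

## Known limitations

* Single-recruit images only; the largest-component rule would silently
  merge or drop organisms in multi-recruit scenes.
* Stage classification is binary; morphologically ambiguous transition
  stages (the known weak point of stage-routed designs) cannot be
  represented more finely.
* The threshold segmenter assumes tissue brighter than its surroundings
  within the box; it is a reference baseline, not a recommended
  production segmenter.
* Nearest-neighbour mask transport is exact only when the segmentation
  frame is at least as large as the original; for originals larger than
  the segmentation frame the resampling bias grows with the boundary
  length.
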