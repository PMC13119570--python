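"""Deterministic generator of recruit-like microscopy fixtures.

Each fixture is a single roughly circular live-tissue region whose
boundary is a low-order harmonic perturbation of a circle, surrounded by
a darker corallite-ring annulus, on a background with a linear
illumination gradient and additive Gaussian noise.  The two developmental
regimes the pipeline routes between are emulated through tissue contrast:
early-stage fixtures have thin, weakly contrasted tissue (default
contrast 0.15) while late-stage fixtures have thick, strongly contrasted
tissue (default 0.6).  The ground-truth mask is the exact rasterization
of the tissue region under a pixel-center inclusion rule, so closed-form
disk areas are available as oracles for the area formula.

Everything is deterministic given the spec seed; datasets expand a single
root seed into per-image seeds by stable hashing, so partial
regeneration reproduces identical fixtures.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import PixelCalibration, physical_area, write_calibrated_tiff, write_mask
from .errors import InvalidArgumentError, InvalidSpecError
from .geometry import Stage, resolve_stage

__all__ = [
    "SyntheticSpec",
    "RecruitFixture",
    "generate_recruit",
    "analytic_disk_fixture",
    "generate_dataset",
    "split_fixtures",
    "default_stage_rule",
    "stable_seed",
]

#: Background plate intensity before illumination gradient.
_BG_LEVEL = 0.35
#: Corallite-ring base intensity (darker than background and tissue).
_CUP_LEVEL = 0.20
#: Default boundary-contrast settings for the two developmental regimes.
EARLY_TISSUE_CONTRAST = 0.15
LATE_TISSUE_CONTRAST = 0.6


def stable_seed(root_seed: int, *keys) -> int:
    """Expand a root seed into a reproducible sub-seed below 2**31."""
    payload = ":".join([str(root_seed), *map(str, keys)]).encode()
    digest = hashlib.blake2b(payload, digest_size=4).digest()
    return int.from_bytes(digest, "big") & 0x7FFFFFFF


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic recruit image.

    ``harmonic_amps[k]`` is the relative amplitude of the cos((k+2)θ)
    boundary harmonic (harmonics 0 and 1 would change scale/centre, so
    perturbation starts at order 2).  ``tissue_contrast`` is the
    intensity step of tissue over the background plate, in [0, 1].
    """

    width: int = 256
    height: int = 256
    um_per_px: float = 3.5
    stage: Stage = Stage.EARLY
    tissue_radius_px: float = 60.0
    harmonic_amps: tuple[float, ...] = (0.04, 0.025)
    cup_ring_width_px: float = 12.0
    tissue_contrast: float | None = None  # None -> stage default
    illum_gradient: float = 0.15
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise InvalidSpecError("frame dimensions must be positive")
        if self.um_per_px <= 0:
            raise InvalidSpecError("pixel size must be positive")
        if self.tissue_radius_px <= 0 or self.cup_ring_width_px < 0:
            raise InvalidSpecError("radii must be positive")
        max_r = self.tissue_radius_px * (1.0 + sum(abs(a) for a in self.harmonic_amps))
        if max_r + self.cup_ring_width_px >= min(self.width, self.height) / 2:
            raise InvalidSpecError(
                "tissue + cup ring must fit inside half the frame"
            )
        if not (0.0 <= self.illum_gradient <= 1.0):
            raise InvalidSpecError("illum_gradient must lie in [0, 1]")
        if self.contrast < 0 or self.contrast > 1:
            raise InvalidSpecError("tissue_contrast must lie in [0, 1]")

    @property
    def contrast(self) -> float:
        if self.tissue_contrast is not None:
            return self.tissue_contrast
        return (
            EARLY_TISSUE_CONTRAST if self.stage is Stage.EARLY else LATE_TISSUE_CONTRAST
        )


@dataclass(frozen=True)
class RecruitFixture:
    """A generated image with its exact ground truth."""

    image: np.ndarray  # uint8 grayscale, height x width
    gt_mask: np.ndarray  # bool, height x width
    calibration: PixelCalibration
    gt_area_um2: float
    stage: Stage


def _tissue_mask(spec: SyntheticSpec, phases: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize the tissue region; returns (mask, radial distance grid)."""
    cy, cx = spec.height / 2.0, spec.width / 2.0
    yy, xx = np.mgrid[0:spec.height, 0:spec.width]
    # pixel-center inclusion rule: pixel (r, c) has centre (c+0.5, r+0.5)
    dx = (xx + 0.5) - cx
    dy = (yy + 0.5) - cy
    dist = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    r_limit = np.full_like(dist, spec.tissue_radius_px)
    for k, amp in enumerate(spec.harmonic_amps):
        r_limit = r_limit + spec.tissue_radius_px * amp * np.cos(
            (k + 2) * theta + phases[k]
        )
    return dist <= r_limit, dist - r_limit


def generate_recruit(spec: SyntheticSpec) -> RecruitFixture:
    """Generate one recruit image plus exact ground truth.

    The image is tissue (background + stage-dependent contrast step) inside
    the harmonic boundary, a darker textured corallite ring around it, a
    linear left-to-right illumination gradient, and additive Gaussian
    noise; fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=max(len(spec.harmonic_amps), 1))
    mask, signed_dist = _tissue_mask(spec, phases)
    cup = (signed_dist > 0) & (signed_dist <= spec.cup_ring_width_px)

    img = np.full((spec.height, spec.width), _BG_LEVEL, dtype=np.float64)
    img[cup] = _CUP_LEVEL + 0.04 * rng.standard_normal(int(cup.sum()))  # skeletal texture
    img[mask] = _BG_LEVEL + spec.contrast * 0.8

    # multiplicative linear illumination ramp across x
    g = spec.illum_gradient
    ramp = np.linspace(1.0 - g / 2.0, 1.0 + g / 2.0, spec.width)[None, :]
    img = img * ramp
    img = img + spec.noise_sd * rng.standard_normal(img.shape)
    img8 = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)

    calib = PixelCalibration(spec.um_per_px, "override")
    area = physical_area(int(mask.sum()), calib)
    return RecruitFixture(img8, mask, calib, area, spec.stage)


def analytic_disk_fixture(
    radius_px: float,
    um_per_px: float,
    frame: tuple[int, int] = (256, 256),
) -> tuple[np.ndarray, np.ndarray, PixelCalibration]:
    """Exact centered-disk rasterization, the closed-form area oracle.

    Returns (image, mask, calibration) with a bright disk on a dark
    background and no randomness; the mask pixel count approximates
    π·r² with O(perimeter) discretization error.
    """
    h, w = int(frame[0]), int(frame[1])
    if radius_px <= 0:
        raise InvalidSpecError("radius must be positive")
    if 2 * radius_px >= min(h, w):
        raise InvalidSpecError(f"disk of radius {radius_px} does not fit {h}x{w}")
    yy, xx = np.mgrid[0:h, 0:w]
    dx = (xx + 0.5) - w / 2.0
    dy = (yy + 0.5) - h / 2.0
    mask = (dx * dx + dy * dy) <= radius_px * radius_px
    img = np.where(mask, np.uint8(204), np.uint8(51))
    return img, mask, PixelCalibration(float(um_per_px), "override")


def default_stage_rule(week: int) -> Stage:
    """Weeks before 8 are early-stage; 8 and later are late-stage."""
    return Stage.EARLY if week < 8 else Stage.LATE


_STAGE_TO_GRADE = {Stage.EARLY: "B", Stage.LATE: "E"}


def generate_dataset(
    out_dir: "str | Path",
    n_per_timepoint: int,
    timepoints: "list[int]",
    growth_factor_per_week: float = 1.05,
    stage_rule=default_stage_rule,
    base_spec: SyntheticSpec | None = None,
    seed: int = 0,
    dataset_name: str = "synthetic",
) -> pd.DataFrame:
    """Generate a time-series fixture directory with manifest.

    Tissue radius grows geometrically, ``growth_factor_per_week**week``
    times the base radius; each image gets its own sub-seed derived by
    stable hashing of (seed, week, index).  Writes calibrated TIFFs under
    ``images/``, ground-truth mask PNGs under ``masks/`` and a
    ``manifest.csv`` with ground-truth areas; returns the manifest frame.
    """
    if n_per_timepoint < 1:
        raise InvalidArgumentError("need at least one image per timepoint")
    if growth_factor_per_week <= 0:
        raise InvalidArgumentError("growth factor must be positive")
    # base radius sized so the default 0-23-week geometric series still
    # fits inside the frame together with the cup ring
    base = base_spec if base_spec is not None else SyntheticSpec(tissue_radius_px=30.0)
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    rows = []
    for week in timepoints:
        stage = resolve_stage(stage_rule(week))
        radius = base.tissue_radius_px * growth_factor_per_week ** week
        for i in range(n_per_timepoint):
            spec = replace(
                base,
                stage=stage,
                tissue_radius_px=radius,
                seed=stable_seed(seed, week, i),
            )
            fx = generate_recruit(spec)
            image_id = f"{dataset_name}_w{week:02d}_{i:03d}"
            img_rel = f"images/{image_id}.tif"
            mask_rel = f"masks/{image_id}.png"
            img_path = out / img_rel
            if img_path.exists():
                raise IOError(f"output collision: {img_path}")
            write_calibrated_tiff(fx.image, fx.calibration, img_path)
            write_mask(fx.gt_mask, out / mask_rel)
            rows.append(
                {
                    "image_id": image_id,
                    "image_path": img_rel,
                    "dataset": dataset_name,
                    "week": week,
                    "grade": _STAGE_TO_GRADE[stage],
                    "um_per_px": spec.um_per_px,
                    "gt_mask_path": mask_rel,
                    "gt_area_um2": fx.gt_area_um2,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def split_fixtures(
    manifest: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/validation/test split of a manifest.

    Seeded shuffle, then contiguous slices with sizes chosen by
    largest-remainder rounding of the fractions.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise InvalidArgumentError("fractions must sum to 1")
    if any(f < 0 for f in fractions):
        raise InvalidArgumentError("fractions must be non-negative")
    n = len(manifest)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    exact = [f * n for f in fractions]
    sizes = [int(np.floor(e)) for e in exact]
    remainders = [e - s for e, s in zip(exact, sizes)]
    while sum(sizes) < n:
        k = int(np.argmax(remainders))
        sizes[k] += 1
        remainders[k] = -1.0
    shuffled = manifest.iloc[order].reset_index(drop=True)
    a, b = sizes[0], sizes[0] + sizes[1]
    return (
        shuffled.iloc[:a].reset_index(drop=True),
        shuffled.iloc[a:b].reset_index(drop=True),
        shuffled.iloc[b:].reset_index(drop=True),
    )
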