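"""The hierarchical measure-one-image chain and batch execution.

Per image: read pixel calibration -> detect on the detection frame
(boxes mapped back to the original frame) -> select the primary
detection -> route by developmental stage to the stage-specific
segmenter -> build the stage-conditional prompt set in the original
frame and rescale it to the segmentation frame -> segment -> map the
mask back to the original frame -> post-process -> pixel count ->
physical area.  Every stage's outcome is recorded; failures become
flagged records rather than silent drops, except an unreadable file
which is an I/O error (and becomes a flagged row at batch level).

Area is always computed on the mask in the original acquisition frame,
so the metadata pixel size applies unmodified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_fill_holes
from skimage.measure import label as cc_label

from . import backends as be
from .calibration import (
    MissingCalibrationError,
    PixelCalibration,
    mask_pixel_count,
    physical_area,
    read_image,
    read_mask,
    read_pixel_size,
)
from .config import PipelineConfig, PostprocessConfig
from .errors import (
    AnisotropicCalibrationError,
    ConfigurationError,
    InvalidArgumentError,
    NoDetectionError,
)
from .geometry import (
    BoundingBox,
    Stage,
    build_prompt_set,
    rescale_prompt_set,
    resolve_stage,
    stage_from_grade,
)
from .resample import resize_nearest

__all__ = [
    "MeasurementRecord",
    "stage_from_grade",
    "select_primary_detection",
    "route_stage",
    "postprocess_mask",
    "measure_image",
    "run_batch",
    "build_registry",
    "CSV_COLUMNS",
    "FLAG_MULTI_DETECTION",
    "FLAG_EMPTY_MASK",
    "FLAG_LOW_CONFIDENCE",
    "FLAG_MISSING_CALIBRATION",
    "FLAG_NO_DETECTION",
    "FLAG_IO_ERROR",
]

FLAG_MULTI_DETECTION = "multi-detection"
FLAG_EMPTY_MASK = "empty-mask"
FLAG_LOW_CONFIDENCE = "low-confidence"
FLAG_MISSING_CALIBRATION = "missing-calibration"
FLAG_NO_DETECTION = "no-detection"
FLAG_IO_ERROR = "io-error"

CSV_COLUMNS = [
    "image_id", "dataset", "week", "stage", "confidence",
    "xmin", "ymin", "xmax", "ymax",
    "a_px", "um_per_px", "area_um2", "flags", "segmenter_id", "config_id",
]


@dataclass
class MeasurementRecord:
    """Per-image morphometry output with its audit trail."""

    image_id: str
    stage: Stage | None = None
    confidence: float | None = None
    box: BoundingBox | None = None
    a_px: int | None = None
    um_per_px: float | None = None
    area_um2: float | None = None
    flags: set[str] = field(default_factory=set)
    segmenter_id: str | None = None
    config_id: str = ""
    dataset: str | None = None
    week: int | None = None
    #: predicted mask in the original frame (not serialized to CSV)
    mask: np.ndarray | None = None

    @property
    def failed(self) -> bool:
        """True when no area could be measured."""
        return self.area_um2 is None

    def to_row(self) -> dict:
        return {
            "image_id": self.image_id,
            "dataset": self.dataset,
            "week": self.week,
            "stage": self.stage.value if self.stage else None,
            "confidence": self.confidence,
            "xmin": self.box.xmin if self.box else None,
            "ymin": self.box.ymin if self.box else None,
            "xmax": self.box.xmax if self.box else None,
            "ymax": self.box.ymax if self.box else None,
            "a_px": self.a_px,
            "um_per_px": self.um_per_px,
            "area_um2": self.area_um2,
            "flags": ";".join(sorted(self.flags)),
            "segmenter_id": self.segmenter_id,
            "config_id": self.config_id,
        }


def select_primary_detection(
    dets: list[be.Detection], confidence_min: float
) -> tuple[be.Detection, set[str]]:
    """Highest-confidence detection at or above the threshold.

    Ties break toward the larger box, then lexicographic corner order.
    Returns the detection plus flags (multi-detection when more than one
    candidate cleared the threshold).  Raises :class:`NoDetectionError`
    carrying the best rejected confidence when nothing clears it.
    """
    above = [d for d in dets if d.confidence >= confidence_min]
    if not above:
        best = max((d.confidence for d in dets), default=None)
        raise NoDetectionError("no detection above confidence threshold", best)
    above.sort(key=lambda d: (-d.confidence, -d.box.area, d.box.corners()))
    flags = {FLAG_MULTI_DETECTION} if len(above) > 1 else set()
    return above[0], flags


def route_stage(stage: Stage, config: PipelineConfig) -> tuple[Stage, str]:
    """Resolve the branch for a detected stage.

    Returns (effective stage, segmenter id).  Under ``invert_routing``
    (the stage-inversion ablation) early detections take the late branch
    — late segmenter *and* late prompt configuration — and vice versa.
    """
    stage = resolve_stage(stage)
    effective = stage
    if config.invert_routing:
        effective = Stage.LATE if stage is Stage.EARLY else Stage.EARLY
    seg_id = (
        config.segmenter_id_early if effective is Stage.EARLY
        else config.segmenter_id_late
    )
    return effective, seg_id


def postprocess_mask(
    mask: np.ndarray, box: BoundingBox, config: PostprocessConfig
) -> tuple[np.ndarray, set[str]]:
    """Clean a predicted mask: box-gated largest component, optional fill.

    With ``largest_component``, only the largest 8-connected component
    intersecting the detection box survives; a component-free result (or
    one below ``min_component_px``) becomes an empty mask with the
    empty-mask flag.  Degenerate inputs never raise.
    """
    mask = np.asarray(mask, dtype=bool)
    flags: set[str] = set()
    h, w = mask.shape
    if config.largest_component:
        labels = cc_label(mask, connectivity=2)
        if labels.max() == 0:
            return np.zeros_like(mask), {FLAG_EMPTY_MASK}
        r0 = max(int(np.floor(box.ymin)), 0)
        r1 = min(int(np.ceil(box.ymax)), h)
        c0 = max(int(np.floor(box.xmin)), 0)
        c1 = min(int(np.ceil(box.xmax)), w)
        in_box = np.unique(labels[r0:r1, c0:c1])
        in_box = in_box[in_box > 0]
        if in_box.size == 0:
            return np.zeros_like(mask), {FLAG_EMPTY_MASK}
        sizes = np.bincount(labels.ravel())
        best = int(in_box[np.argmax(sizes[in_box])])
        mask = labels == best
    if config.fill_holes:
        mask = binary_fill_holes(mask)
    if not mask.any() or int(mask.sum()) < config.min_component_px:
        return np.zeros_like(mask), flags | {FLAG_EMPTY_MASK}
    return mask, flags


def _bind(backend, image_id: str) -> None:
    hook = getattr(backend, "bind", None)
    if callable(hook):
        hook(image_id)


def measure_image(
    image_path: "str | Path",
    config: PipelineConfig,
    registry: be.BackendRegistry,
    image_id: str | None = None,
    calibration_override: float | None = None,
    dataset: str | None = None,
    week: int | None = None,
    keep_mask: bool = False,
) -> MeasurementRecord:
    """Run the full measurement chain on one image.

    Deterministic given the config and seed-bearing backends.  Stage
    errors (missing calibration, no detection, empty mask) become flags
    on the returned record; an unreadable file raises ``OSError``.
    """
    path = Path(image_path)
    rec = MeasurementRecord(
        image_id=image_id or path.stem,
        config_id=config.config_id,
        dataset=dataset,
        week=week,
    )

    try:
        calib = read_pixel_size(path, override=calibration_override)
        rec.um_per_px = calib.s
    except (MissingCalibrationError, AnisotropicCalibrationError):
        calib = None
        rec.flags.add(FLAG_MISSING_CALIBRATION)

    image = read_image(path)
    orig_h, orig_w = image.shape[0], image.shape[1]

    detector = registry.detector(config.detector_id)
    _bind(detector, rec.image_id)
    det_frame = resize_nearest(image, (config.detect_resize, config.detect_resize))
    dets = detector.detect(det_frame)
    try:
        primary, det_flags = select_primary_detection(dets, config.confidence_min)
    except NoDetectionError as err:
        rec.flags.add(FLAG_NO_DETECTION)
        if err.best_confidence is not None:
            rec.flags.add(FLAG_LOW_CONFIDENCE)
        return rec
    rec.flags |= det_flags
    rec.confidence = primary.confidence
    rec.stage = primary.stage
    box = primary.box.scaled(orig_w, orig_h)  # back to the original frame
    rec.box = box

    effective_stage, seg_id = route_stage(primary.stage, config)
    rec.segmenter_id = seg_id
    segmenter = registry.segmenter(seg_id)
    _bind(segmenter, rec.image_id)

    prompt_stage = effective_stage
    if effective_stage is Stage.EARLY and not config.early_background_points:
        prompt_stage = Stage.LATE  # box-only prompt configuration
    prompts = build_prompt_set(box, prompt_stage)
    prompts_seg = rescale_prompt_set(prompts, config.segment_resize, config.segment_resize)

    seg_frame = resize_nearest(image, (config.segment_resize, config.segment_resize))
    mask_seg = np.asarray(segmenter.segment(seg_frame, prompts_seg), dtype=bool)
    if mask_seg.shape[:2] != seg_frame.shape[:2]:
        raise ConfigurationError(
            f"segmenter {seg_id!r} returned mask of shape {mask_seg.shape}, "
            f"expected {seg_frame.shape[:2]}"
        )
    mask = resize_nearest(mask_seg, (orig_h, orig_w))
    mask, pp_flags = postprocess_mask(mask, box, config.postprocess)
    rec.flags |= pp_flags

    rec.a_px = mask_pixel_count(mask)
    if keep_mask:
        rec.mask = mask
    if FLAG_EMPTY_MASK in rec.flags:
        return rec
    if calib is not None:
        rec.area_um2 = physical_area(rec.a_px, calib)
    return rec


def run_batch(
    manifest: "pd.DataFrame | str | Path",
    config: PipelineConfig,
    registry: be.BackendRegistry,
    root: "str | Path | None" = None,
    out_csv: "str | Path | None" = None,
    keep_masks: bool = False,
) -> tuple[pd.DataFrame, list[MeasurementRecord]]:
    """Measure every image in a manifest, in manifest order.

    The manifest needs an ``image_path`` column; ``image_id``, ``grade``,
    ``week``, ``dataset`` and ``um_per_px`` columns are honoured when
    present.  Unreadable images become flagged rows, never silent drops.
    Returns (records table, record objects); identical inputs and seeds
    give a byte-identical CSV.
    """
    if isinstance(manifest, (str, Path)):
        manifest_path = Path(manifest)
        root = Path(root) if root is not None else manifest_path.parent
        manifest = pd.read_csv(manifest_path)
    else:
        root = Path(root) if root is not None else Path(".")
    if len(manifest) == 0:
        raise InvalidArgumentError("empty manifest")
    if "image_path" not in manifest.columns:
        raise InvalidArgumentError("manifest needs an image_path column")

    records: list[MeasurementRecord] = []
    for _, row in manifest.iterrows():
        rel = str(row["image_path"])
        path = root / rel if not Path(rel).is_absolute() else Path(rel)
        image_id = str(row["image_id"]) if "image_id" in row and pd.notna(row.get("image_id")) else Path(rel).stem
        dataset = str(row["dataset"]) if "dataset" in row and pd.notna(row.get("dataset")) else None
        week = int(row["week"]) if "week" in row and pd.notna(row.get("week")) else None
        override = float(row["um_per_px"]) if "um_per_px" in row and pd.notna(row.get("um_per_px")) else None
        try:
            rec = measure_image(
                path, config, registry,
                image_id=image_id, calibration_override=override,
                dataset=dataset, week=week, keep_mask=keep_masks,
            )
        except OSError:
            rec = MeasurementRecord(
                image_id=image_id, config_id=config.config_id,
                dataset=dataset, week=week, flags={FLAG_IO_ERROR},
            )
        records.append(rec)

    table = pd.DataFrame([r.to_row() for r in records], columns=CSV_COLUMNS)
    if out_csv is not None:
        out_csv = Path(out_csv)
        out_csv.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_csv, index=False)
    return table, records


def build_registry(
    config: PipelineConfig,
    manifest: pd.DataFrame,
    root: "str | Path" = ".",
    seed: int = 0,
) -> be.BackendRegistry:
    """Construct built-in backends for a fixture manifest.

    Backend ids resolve by prefix: detector ids starting with ``oracle``
    or ``mock`` become a manifest-bound mock detector (ground-truth boxes
    derived from the manifest's ``gt_mask_path`` masks, stage from
    ``grade``); segmenter ids starting with ``threshold`` become the
    classical Otsu segmenter, anything else a manifest-bound perturbation
    segmenter.  Options come from ``config.detector_options``
    (``jitter_px``, ``box_pad_px``) and ``config.segmenter_options``
    (``delta_px`` globally or ``"<id>.delta_px"`` per backend id).
    """
    root = Path(root)
    need_gt = ("gt_mask_path" in manifest.columns)
    gt_boxes: dict[str, tuple[BoundingBox, Stage]] = {}
    gt_masks: dict[str, Path] = {}
    if need_gt:
        pad = float(config.detector_options.get("box_pad_px", 2.0))
        for _, row in manifest.iterrows():
            image_id = str(row.get("image_id") or Path(str(row["image_path"])).stem)
            mask_path = root / str(row["gt_mask_path"])
            gt_masks[image_id] = mask_path
            mask = read_mask(mask_path)
            stage = stage_from_grade(row["grade"]) if "grade" in row and pd.notna(row.get("grade")) else Stage.LATE
            gt_boxes[image_id] = (be.box_from_mask(mask, pad_px=pad), stage)

    registry = be.BackendRegistry()

    det_id = config.detector_id
    if det_id.startswith(("oracle", "mock")):
        if not need_gt:
            raise ConfigurationError(
                f"detector {det_id!r} needs gt_mask_path in the manifest"
            )
        registry.add_detector(
            det_id,
            be.ManifestMockDetector(
                gt_boxes,
                jitter_px=float(config.detector_options.get("jitter_px", 0.0)),
                seed=seed,
            ),
        )
    else:
        raise ConfigurationError(f"no built-in detector for id {det_id!r}")

    opts = config.segmenter_options
    for sid in {config.segmenter_id_early, config.segmenter_id_late}:
        if sid.startswith("threshold"):
            registry.add_segmenter(
                sid, be.ThresholdSegmenter(
                    min_component_px=config.postprocess.min_component_px
                )
            )
        else:
            if not need_gt:
                raise ConfigurationError(
                    f"segmenter {sid!r} needs gt_mask_path in the manifest"
                )
            delta = opts.get(f"{sid}.delta_px", opts.get("delta_px", 0.0))
            registry.add_segmenter(
                sid, be.ManifestPerturbationSegmenter(gt_masks, delta_px=delta)
            )
    return registry
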