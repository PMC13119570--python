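"""Detector and segmenter contracts plus deterministic reference backends.

The pipeline only ever talks to two small contracts:

* a detector maps an image to a list of :class:`Detection` (box + stage
  + confidence), boxes expressed in the frame of the image it was given;
* a segmenter maps (image, :class:`~coralmorph.geometry.PromptSet`) to a
  binary mask in that same frame.

Trained networks would sit behind these contracts; this package ships
deterministic desk-scale stand-ins instead: a mock detector that jitters
a known ground-truth box, a perturbation segmenter that dilates/erodes a
known ground-truth mask by a controlled number of pixels (emulating the
over-/under-segmentation regimes seen in real recruits), and a classical
intensity-threshold segmenter that actually honours the prompt geometry.

Backends that need per-image ground truth at batch scale (the manifest-
bound variants) expose an optional ``bind(image_id)`` hook which the
pipeline calls before each image; the detect/segment contracts stay pure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol, runtime_checkable

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk, erosion

from .calibration import read_mask
from .errors import ConfigurationError, InvalidArgumentError, InvalidGeometryError
from .geometry import BoundingBox, PromptSet, Stage, resolve_stage
from .resample import resize_nearest
from .synthetic import stable_seed

__all__ = [
    "Detection",
    "Detector",
    "Segmenter",
    "MockDetector",
    "PerturbationSegmenter",
    "ThresholdSegmenter",
    "ManifestMockDetector",
    "ManifestPerturbationSegmenter",
    "BackendRegistry",
    "box_from_mask",
]


@dataclass(frozen=True)
class Detection:
    """One detected recruit: localization box, routing stage, confidence."""

    box: BoundingBox
    stage: Stage
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise InvalidArgumentError(
                f"confidence must lie in [0, 1], got {self.confidence}"
            )


@runtime_checkable
class Detector(Protocol):
    def detect(self, image: np.ndarray) -> list[Detection]: ...


@runtime_checkable
class Segmenter(Protocol):
    def segment(self, image: np.ndarray, prompts: PromptSet) -> np.ndarray: ...


def box_from_mask(mask: np.ndarray, pad_px: float = 0.0) -> BoundingBox:
    """Tight bounding box of a mask's true pixels, optionally padded.

    The box is expressed in continuous coordinates: a true pixel at
    (row r, col c) contributes the extent [c, c+1) x [r, r+1).
    """
    mask = np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise InvalidGeometryError("cannot box an empty mask")
    h, w = mask.shape
    return BoundingBox(
        max(0.0, cols[0] - pad_px),
        max(0.0, rows[0] - pad_px),
        min(float(w), cols[-1] + 1 + pad_px),
        min(float(h), rows[-1] + 1 + pad_px),
        w,
        h,
    )


def _rescale_to_image(box: BoundingBox, image: np.ndarray) -> BoundingBox:
    h, w = image.shape[0], image.shape[1]
    if (w, h) == (box.image_width, box.image_height):
        return box
    return box.scaled(w, h)


class MockDetector:
    """Test double for the detection stage: a known box plus uniform jitter.

    Corner noise is drawn once at construction (uniform in
    [-jitter, +jitter] per corner, clamped to the frame, re-drawn up to
    100 times if the box degenerates), so repeated ``detect`` calls and
    repeated constructions with the same seed agree exactly.  The box is
    rescaled to the frame of whatever image is passed in.
    """

    def __init__(
        self,
        gt_box: BoundingBox,
        stage: "Stage | str",
        jitter_px: float = 0.0,
        seed: int = 0,
        confidence: float = 0.99,
    ):
        if jitter_px < 0:
            raise InvalidArgumentError("jitter must be non-negative")
        self.stage = resolve_stage(stage)
        self.confidence = confidence
        rng = np.random.default_rng(seed)
        self.box = self._jitter_box(gt_box, jitter_px, rng)

    @staticmethod
    def _jitter_box(gt: BoundingBox, jitter: float, rng: np.random.Generator) -> BoundingBox:
        if jitter == 0:
            return gt
        for _ in range(100):
            dx0, dy0, dx1, dy1 = rng.uniform(-jitter, jitter, size=4)
            xmin = min(max(gt.xmin + dx0, 0.0), gt.image_width)
            ymin = min(max(gt.ymin + dy0, 0.0), gt.image_height)
            xmax = min(max(gt.xmax + dx1, 0.0), gt.image_width)
            ymax = min(max(gt.ymax + dy1, 0.0), gt.image_height)
            if xmin < xmax and ymin < ymax:
                return BoundingBox(xmin, ymin, xmax, ymax, gt.image_width, gt.image_height)
        raise InvalidGeometryError("jitter degenerates the box; reduce jitter_px")

    def detect(self, image: np.ndarray) -> list[Detection]:
        return [Detection(_rescale_to_image(self.box, image), self.stage, self.confidence)]


def _morph(mask: np.ndarray, delta_px: float) -> np.ndarray:
    r = int(round(delta_px))
    if r == 0:
        return np.asarray(mask, dtype=bool).copy()
    mask = np.asarray(mask, dtype=bool)
    foot = disk(abs(r))  # symmetric footprint: no mirroring concerns
    if r > 0:
        return dilation(mask, foot)
    return erosion(mask, foot)


class PerturbationSegmenter:
    """Controlled-error oracle: ground truth dilated/eroded by round(delta) px.

    ``delta_px > 0`` emulates over-segmentation (e.g. leakage into the
    corallite cup), ``delta_px < 0`` under-segmentation, ``0`` the
    identity.  Morphology is applied in the ground-truth frame; the
    result is resampled to the frame of the image passed to ``segment``.
    ``empty_result`` is set when erosion empties the mask.
    """

    def __init__(self, gt_mask: np.ndarray, delta_px: float = 0.0):
        gt_mask = np.asarray(gt_mask, dtype=bool)
        if gt_mask.ndim != 2:
            raise InvalidArgumentError("ground-truth mask must be 2-D")
        self.delta_px = float(delta_px)
        self.mask = _morph(gt_mask, delta_px)
        self.empty_result = not self.mask.any()

    def segment(self, image: np.ndarray, prompts: PromptSet) -> np.ndarray:
        return resize_nearest(self.mask, (image.shape[0], image.shape[1]))


class ThresholdSegmenter:
    """Classical prompt-aware baseline: Otsu threshold inside the box.

    Converts to grayscale, thresholds within the prompt box, then
    (a) vetoes any connected component containing a background prompt
    point — the deterministic analogue of a negative prompt suppressing
    mask growth into non-tissue regions, (b) keeps the largest remaining
    component, and (c) discards it if smaller than ``min_component_px``.
    The returned mask lives in the full image frame.
    """

    def __init__(self, method: str = "otsu", min_component_px: int = 16):
        if method != "otsu":
            raise ConfigurationError(f"unknown threshold method {method!r}")
        self.method = method
        self.min_component_px = int(min_component_px)
        self.low_confidence = False

    def segment(self, image: np.ndarray, prompts: PromptSet) -> np.ndarray:
        img = np.asarray(image, dtype=np.float64)
        if img.ndim == 3:
            img = img.mean(axis=2)
        h, w = img.shape
        box = prompts.box
        r0, r1 = int(np.floor(box.ymin)), int(np.ceil(box.ymax))
        c0, c1 = int(np.floor(box.xmin)), int(np.ceil(box.xmax))
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, h), min(c1, w)
        if r1 <= r0 or c1 <= c0:
            raise InvalidGeometryError("prompt box crops to an empty region")
        crop = img[r0:r1, c0:c1]

        self.low_confidence = False
        if np.ptp(crop) < 1e-9:  # no contrast at all
            self.low_confidence = True
            return np.zeros((h, w), dtype=bool)
        fg = crop > threshold_otsu(crop)
        labels = cc_label(fg, connectivity=2)

        vetoed: set[int] = set()
        for p in prompts.points:
            if p.label != "background":
                continue
            rr = int(min(max(np.floor(p.y - r0), 0), crop.shape[0] - 1))
            cc = int(min(max(np.floor(p.x - c0), 0), crop.shape[1] - 1))
            lab = labels[rr, cc]
            if lab > 0:
                vetoed.add(int(lab))
        for lab in vetoed:
            fg[labels == lab] = False

        labels = cc_label(fg, connectivity=2)
        if labels.max() == 0:
            return np.zeros((h, w), dtype=bool)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        best = int(sizes.argmax())
        if sizes[best] < self.min_component_px:
            return np.zeros((h, w), dtype=bool)
        out = np.zeros((h, w), dtype=bool)
        out[r0:r1, c0:c1] = labels == best
        return out


class ManifestMockDetector:
    """Mock detector over a fixture set, keyed by image id via ``bind``.

    ``gt`` maps image_id -> (BoundingBox, stage).  Jitter is drawn from a
    per-image seed derived by stable hashing of (seed, image_id), so
    batch re-runs are reproducible regardless of visiting order.
    """

    def __init__(self, gt: dict, jitter_px: float = 0.0, seed: int = 0,
                 confidence: float = 0.99):
        self.gt = dict(gt)
        self.jitter_px = float(jitter_px)
        self.seed = int(seed)
        self.confidence = confidence
        self._current: str | None = None

    def bind(self, image_id: str) -> None:
        if image_id not in self.gt:
            raise ConfigurationError(f"no ground truth for image {image_id!r}")
        self._current = image_id

    def detect(self, image: np.ndarray) -> list[Detection]:
        if self._current is None:
            raise ConfigurationError("ManifestMockDetector used without bind()")
        box, stage = self.gt[self._current]
        rng = np.random.default_rng(stable_seed(self.seed, self._current))
        jittered = MockDetector._jitter_box(box, self.jitter_px, rng)
        return [Detection(_rescale_to_image(jittered, image),
                          resolve_stage(stage), self.confidence)]


class ManifestPerturbationSegmenter:
    """Perturbation segmenter over a fixture set, keyed by ``bind``.

    ``masks`` maps image_id -> ground-truth mask (array or PNG path);
    ``delta_px`` is a scalar, a per-image mapping, or a callable
    image_id -> delta.
    """

    def __init__(self, masks: dict, delta_px=0.0):
        self.masks = dict(masks)
        self.delta_px = delta_px
        self._current: str | None = None
        self._cache: dict[str, np.ndarray] = {}

    def bind(self, image_id: str) -> None:
        if image_id not in self.masks:
            raise ConfigurationError(f"no ground-truth mask for image {image_id!r}")
        self._current = image_id

    def _delta_for(self, image_id: str) -> float:
        d = self.delta_px
        if callable(d):
            return float(d(image_id))
        if isinstance(d, dict):
            return float(d[image_id])
        return float(d)

    def segment(self, image: np.ndarray, prompts: PromptSet) -> np.ndarray:
        if self._current is None:
            raise ConfigurationError("ManifestPerturbationSegmenter used without bind()")
        if self._current not in self._cache:
            gt = self.masks[self._current]
            if isinstance(gt, (str, Path)):
                gt = read_mask(gt)
            self._cache[self._current] = _morph(gt, self._delta_for(self._current))
        return resize_nearest(self._cache[self._current],
                              (image.shape[0], image.shape[1]))


class BackendRegistry:
    """String-keyed registry binding config backend ids to instances."""

    def __init__(self) -> None:
        self._detectors: dict[str, Detector] = {}
        self._segmenters: dict[str, Segmenter] = {}

    def add_detector(self, backend_id: str, detector: Detector) -> "BackendRegistry":
        self._detectors[backend_id] = detector
        return self

    def add_segmenter(self, backend_id: str, segmenter: Segmenter) -> "BackendRegistry":
        self._segmenters[backend_id] = segmenter
        return self

    def detector(self, backend_id: str) -> Detector:
        try:
            return self._detectors[backend_id]
        except KeyError:
            raise ConfigurationError(f"unregistered detector id {backend_id!r}")

    def segmenter(self, backend_id: str) -> Segmenter:
        try:
            return self._segmenters[backend_id]
        except KeyError:
            raise ConfigurationError(f"unregistered segmenter id {backend_id!r}")
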