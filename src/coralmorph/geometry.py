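"""Bounding-box and prompt-point geometry.

Coordinates are continuous pixel coordinates in the image frame: origin at
the top-left corner, x increasing rightward, y increasing downward, and the
area of pixel (row 0, col 0) spanning [0,1)x[0,1).  Boxes are stored as
continuous corner values in the *original* image frame, never in a resized
model frame; prompts are constructed there and rescaled per axis when the
segmenter operates on a resized frame.

The prompt strategy is stage-conditional: early-stage recruits (thin,
low-contrast tissue confined to the corallite cup) get the detection box
plus four *background* (negative) points placed at the midpoints of the box
edges, which suppress mask leakage into the cup and substrate; late-stage
recruits get the box only.  No foreground points are ever used.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .errors import ConfigurationError, InvalidArgumentError, InvalidGeometryError

__all__ = [
    "Stage",
    "GRADE_TO_STAGE",
    "stage_from_grade",
    "resolve_stage",
    "BoundingBox",
    "PointPrompt",
    "PromptSet",
    "box_center",
    "edge_midpoint_background_points",
    "build_prompt_set",
    "rescale_prompt_set",
]


class Stage(str, enum.Enum):
    """Binary developmental stage used for model routing."""

    EARLY = "early"
    LATE = "late"


#: Qualitative pigmentation/maturity grades A-G collapse onto the binary
#: routing label: A-C are early-stage, D-G late-stage.
GRADE_TO_STAGE: dict[str, Stage] = {
    "A": Stage.EARLY,
    "B": Stage.EARLY,
    "C": Stage.EARLY,
    "D": Stage.LATE,
    "E": Stage.LATE,
    "F": Stage.LATE,
    "G": Stage.LATE,
}


def stage_from_grade(grade: str) -> Stage:
    """Map a developmental grade (A-G) to its routing stage."""
    try:
        return GRADE_TO_STAGE[str(grade).strip().upper()]
    except KeyError:
        raise InvalidArgumentError(f"unknown developmental grade {grade!r}")


def resolve_stage(stage: "Stage | str") -> Stage:
    """Coerce a Stage, a stage name, or a grade letter to a Stage."""
    if isinstance(stage, Stage):
        return stage
    s = str(stage).strip()
    if s.lower() in (Stage.EARLY.value, Stage.LATE.value):
        return Stage(s.lower())
    if s.upper() in GRADE_TO_STAGE:
        return GRADE_TO_STAGE[s.upper()]
    raise ConfigurationError(f"cannot resolve stage from {stage!r}")


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned detection rectangle in original-image pixel coordinates."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    image_width: int
    image_height: int

    def __post_init__(self) -> None:
        if self.image_width <= 0 or self.image_height <= 0:
            raise InvalidGeometryError(
                f"non-positive frame {self.image_width}x{self.image_height}"
            )
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise InvalidGeometryError(
                f"degenerate box ({self.xmin},{self.ymin},{self.xmax},{self.ymax})"
            )
        if not (
            0 <= self.xmin
            and self.xmax <= self.image_width
            and 0 <= self.ymin
            and self.ymax <= self.image_height
        ):
            raise InvalidGeometryError(
                f"box ({self.xmin},{self.ymin},{self.xmax},{self.ymax}) "
                f"outside {self.image_width}x{self.image_height} frame"
            )

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    def corners(self) -> tuple[float, float, float, float]:
        return (self.xmin, self.ymin, self.xmax, self.ymax)

    def scaled(self, to_width: int, to_height: int) -> "BoundingBox":
        """Per-axis affine rescale into a target frame."""
        if to_width <= 0 or to_height <= 0:
            raise InvalidArgumentError("target frame dimensions must be positive")
        fx = to_width / self.image_width
        fy = to_height / self.image_height
        return BoundingBox(
            self.xmin * fx,
            self.ymin * fy,
            self.xmax * fx,
            self.ymax * fy,
            to_width,
            to_height,
        )


@dataclass(frozen=True)
class PointPrompt:
    """A labeled point prompt; ``background`` marks a location to exclude."""

    x: float
    y: float
    label: str  # "foreground" | "background"

    def __post_init__(self) -> None:
        if self.label not in ("foreground", "background"):
            raise InvalidArgumentError(f"unknown point label {self.label!r}")


def box_center(box: BoundingBox) -> tuple[float, float]:
    """Continuous box center ((xmin+xmax)/2, (ymin+ymax)/2), no rounding."""
    return ((box.xmin + box.xmax) / 2.0, (box.ymin + box.ymax) / 2.0)


def edge_midpoint_background_points(box: BoundingBox) -> list[PointPrompt]:
    """Four background points at the box-edge midpoints.

    Fixed order: top (xc, ymin), bottom (xc, ymax), left (xmin, yc),
    right (xmax, yc), where (xc, yc) is the box center.
    """
    xc, yc = box_center(box)
    return [
        PointPrompt(xc, box.ymin, "background"),
        PointPrompt(xc, box.ymax, "background"),
        PointPrompt(box.xmin, yc, "background"),
        PointPrompt(box.xmax, yc, "background"),
    ]


@dataclass(frozen=True)
class PromptSet:
    """The stage-conditional input contract for any segmenter backend."""

    box: BoundingBox
    points: tuple[PointPrompt, ...]
    stage: Stage
    frame_width: int
    frame_height: int

    def __post_init__(self) -> None:
        if (self.frame_width, self.frame_height) != (
            self.box.image_width,
            self.box.image_height,
        ):
            raise InvalidGeometryError("prompt frame does not match box frame")
        if any(p.label == "foreground" for p in self.points):
            raise InvalidGeometryError("foreground points are never used")
        if self.stage is Stage.LATE and self.points:
            raise InvalidGeometryError("late-stage prompt sets carry no points")
        if self.stage is Stage.EARLY and len(self.points) != 4:
            raise InvalidGeometryError("early-stage prompt sets carry exactly 4 points")

    def to_dict(self) -> dict:
        return {
            "box": {
                "xmin": self.box.xmin,
                "ymin": self.box.ymin,
                "xmax": self.box.xmax,
                "ymax": self.box.ymax,
            },
            "points": [{"x": p.x, "y": p.y, "label": p.label} for p in self.points],
            "stage": self.stage.value,
            "frame": {"w": self.frame_width, "h": self.frame_height},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PromptSet":
        w, h = int(d["frame"]["w"]), int(d["frame"]["h"])
        box = BoundingBox(
            d["box"]["xmin"], d["box"]["ymin"], d["box"]["xmax"], d["box"]["ymax"], w, h
        )
        points = tuple(
            PointPrompt(p["x"], p["y"], p["label"]) for p in d["points"]
        )
        return cls(box, points, Stage(d["stage"]), w, h)


def build_prompt_set(box: BoundingBox, stage: "Stage | str") -> PromptSet:
    """Build the stage-conditional prompt set for a detection box.

    Early stage: box plus the four edge-midpoint background points.
    Late stage: box only.
    """
    st = resolve_stage(stage)
    points: tuple[PointPrompt, ...]
    if st is Stage.EARLY:
        points = tuple(edge_midpoint_background_points(box))
    else:
        points = ()
    return PromptSet(box, points, st, box.image_width, box.image_height)


def rescale_prompt_set(ps: PromptSet, to_width: int, to_height: int) -> PromptSet:
    """Affinely rescale a prompt set into a target frame, per axis.

    Midpoints map to midpoints under per-axis affine scaling, so the
    rescaled set satisfies the same stage invariants.
    """
    if to_width <= 0 or to_height <= 0:
        raise InvalidArgumentError("target frame dimensions must be positive")
    fx = to_width / ps.frame_width
    fy = to_height / ps.frame_height
    box = ps.box.scaled(to_width, to_height)
    points = tuple(PointPrompt(p.x * fx, p.y * fy, p.label) for p in ps.points)
    return PromptSet(box, points, ps.stage, to_width, to_height)
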