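import json

import pytest
from hypothesis import given, settings, strategies as st

from coralmorph.errors import (
    ConfigurationError,
    InvalidArgumentError,
    InvalidGeometryError,
)
from coralmorph.geometry import (
    BoundingBox,
    PromptSet,
    Stage,
    box_center,
    build_prompt_set,
    edge_midpoint_background_points,
    rescale_prompt_set,
    stage_from_grade,
)


def box(xmin, ymin, xmax, ymax, w=1000, h=1000):
    return BoundingBox(xmin, ymin, xmax, ymax, w, h)


@st.composite
def valid_boxes(draw):
    w = draw(st.integers(min_value=2, max_value=4096))
    h = draw(st.integers(min_value=2, max_value=4096))
    x0 = draw(st.floats(min_value=0, max_value=w - 1, allow_nan=False))
    x1 = x0 + draw(st.floats(min_value=0.01, max_value=w - x0))
    y0 = draw(st.floats(min_value=0, max_value=h - 1, allow_nan=False))
    y1 = y0 + draw(st.floats(min_value=0.01, max_value=h - y0))
    return BoundingBox(x0, y0, x1, y1, w, h)


class TestBoxCenter:
    @pytest.mark.parametrize(
        "corners, expected",
        [((0, 0, 10, 20), (5, 10)), ((2, 3, 5, 9), (3.5, 6))],
    )
    def test_midpoint_formula(self, corners, expected):
        assert box_center(box(*corners)) == expected

    def test_degenerate_box_rejected(self):
        with pytest.raises(InvalidGeometryError):
            box(7, 7, 7, 9)

    def test_box_outside_frame_rejected(self):
        with pytest.raises(InvalidGeometryError):
            box(-1, 0, 10, 10)
        with pytest.raises(InvalidGeometryError):
            box(0, 0, 10, 10, w=5, h=5)


class TestEdgeMidpoints:
    @pytest.mark.parametrize(
        "corners, expected",
        [
            ((0, 0, 10, 20), [(5, 0), (5, 20), (0, 10), (10, 10)]),
            ((100, 40, 300, 240), [(200, 40), (200, 240), (100, 140), (300, 140)]),
        ],
    )
    def test_four_points_fixed_order(self, corners, expected):
        pts = edge_midpoint_background_points(box(*corners))
        assert [(p.x, p.y) for p in pts] == expected
        assert all(p.label == "background" for p in pts)

    @settings(derandomize=True, max_examples=200)
    @given(valid_boxes())
    def test_points_lie_on_perimeter(self, b):
        for p in edge_midpoint_background_points(b):
            on_x_edge = p.x in (b.xmin, b.xmax) and b.ymin <= p.y <= b.ymax
            on_y_edge = p.y in (b.ymin, b.ymax) and b.xmin <= p.x <= b.xmax
            assert on_x_edge or on_y_edge


class TestBuildPromptSet:
    def test_early_gets_four_background_points(self):
        ps = build_prompt_set(box(0, 0, 10, 20), Stage.EARLY)
        assert len(ps.points) == 4
        assert all(p.label == "background" for p in ps.points)

    def test_late_gets_box_only(self):
        ps = build_prompt_set(box(0, 0, 10, 20), Stage.LATE)
        assert ps.points == ()

    def test_grade_resolves_stage(self):
        assert len(build_prompt_set(box(0, 0, 10, 20), "B").points) == 4
        assert len(build_prompt_set(box(0, 0, 10, 20), "D").points) == 0

    def test_unresolvable_stage_is_config_error(self):
        with pytest.raises(ConfigurationError):
            build_prompt_set(box(0, 0, 10, 20), "middling")

    @settings(derandomize=True, max_examples=200)
    @given(valid_boxes(), st.sampled_from([Stage.EARLY, Stage.LATE]))
    def test_point_count_invariant(self, b, stage):
        ps = build_prompt_set(b, stage)
        assert len(ps.points) == (4 if stage is Stage.EARLY else 0)
        if stage is Stage.EARLY:
            expected = edge_midpoint_background_points(b)
            assert [(p.x, p.y) for p in ps.points] == [
                (p.x, p.y) for p in expected
            ]


class TestRescale:
    def test_linear_scaling(self):
        ps = build_prompt_set(box(0, 0, 10, 20, w=100, h=200), Stage.LATE)
        out = rescale_prompt_set(ps, 1024, 1024)
        assert out.box.corners() == (0, 0, 102.4, 102.4)

    def test_identity_rescale(self):
        ps = build_prompt_set(box(3, 4, 9, 11, w=64, h=64), Stage.EARLY)
        assert rescale_prompt_set(ps, 64, 64) == ps

    def test_midpoints_map_to_midpoints(self):
        # recompute midpoints in the target frame, compare to scaled points
        ps = rescale_prompt_set(
            build_prompt_set(box(10, 10, 30, 50, w=64, h=64), Stage.EARLY), 1024, 1024
        )
        recomputed = edge_midpoint_background_points(ps.box)
        assert [(p.x, p.y) for p in ps.points] == pytest.approx(
            [(p.x, p.y) for p in recomputed]
        )

    @settings(derandomize=True, max_examples=100)
    @given(valid_boxes())
    def test_roundtrip_within_tolerance(self, b):
        ps = build_prompt_set(b, Stage.EARLY)
        back = rescale_prompt_set(rescale_prompt_set(ps, 1024, 1024),
                                  b.image_width, b.image_height)
        for got, want in zip(back.box.corners(), b.corners()):
            assert got == pytest.approx(want, abs=1e-9, rel=1e-9)

    def test_nonpositive_target_rejected(self):
        ps = build_prompt_set(box(0, 0, 10, 20), Stage.LATE)
        with pytest.raises(InvalidArgumentError):
            rescale_prompt_set(ps, 0, 100)


class TestSerialization:
    def test_json_roundtrip_stable_fields(self):
        ps = build_prompt_set(box(2, 3, 8, 13, w=50, h=60), Stage.EARLY)
        d = json.loads(json.dumps(ps.to_dict()))
        assert set(d) == {"box", "points", "stage", "frame"}
        assert PromptSet.from_dict(d) == ps


class TestStageTaxonomy:
    @pytest.mark.parametrize("grade, stage", [
        ("A", Stage.EARLY), ("B", Stage.EARLY), ("C", Stage.EARLY),
        ("D", Stage.LATE), ("E", Stage.LATE), ("F", Stage.LATE), ("G", Stage.LATE),
    ])
    def test_grade_mapping(self, grade, stage):
        assert stage_from_grade(grade) is stage

    def test_unknown_grade(self):
        with pytest.raises(InvalidArgumentError):
            stage_from_grade("H")

    def test_no_foreground_points_ever(self):
        b = box(0, 0, 10, 10)
        from coralmorph.geometry import PointPrompt
        with pytest.raises(InvalidGeometryError):
            PromptSet(b, (PointPrompt(5, 0, "foreground"),) * 4, Stage.EARLY,
                      b.image_width, b.image_height)
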