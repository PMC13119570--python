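import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coralmorph.errors import InvalidArgumentError, JoinError
from coralmorph.geometry import BoundingBox
from coralmorph.backends import Detection
from coralmorph.geometry import Stage
from coralmorph.metrics import (
    aar,
    area_ratio,
    compare_runs,
    delta_aar,
    delta_abs_bias,
    detection_pr,
    iou,
    mean_std_ar,
    median_ar,
    stratified_report,
)


def b(x0, y0, x1, y1, w=100, h=100):
    return BoundingBox(x0, y0, x1, y1, w, h)


class TestIoU:
    def test_identical(self):
        m = np.zeros((10, 10), bool)
        m[2:6, 2:6] = True
        assert iou(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((10, 10), bool); a[0:2, 0:2] = True
        c = np.zeros((10, 10), bool); c[5:7, 5:7] = True
        assert iou(a, c) == 0.0

    def test_nested_half(self):
        a = np.zeros((30, 30), bool); a[0:10, 0:10] = True
        c = np.zeros((30, 30), bool); c[0:10, 0:20] = True
        assert iou(a, c) == 0.5

    def test_empty_conventions(self):
        e = np.zeros((5, 5), bool)
        f = np.ones((5, 5), bool)
        assert iou(e, e) == 1.0
        assert iou(e, f) == 0.0

    def test_symmetry_and_shape_check(self):
        a = np.random.default_rng(0).random((8, 8)) > 0.5
        c = np.random.default_rng(1).random((8, 8)) > 0.5
        assert iou(a, c) == iou(c, a)
        with pytest.raises(InvalidArgumentError):
            iou(a, np.zeros((4, 4), bool))


class TestAreaRatio:
    @pytest.mark.parametrize("pred, true, expected",
                             [(400, 400, 1.0), (520, 500, 1.04), (0, 500, 0.0)])
    def test_values(self, pred, true, expected):
        assert area_ratio(pred, true) == pytest.approx(expected)

    def test_nonpositive_truth_rejected(self):
        with pytest.raises(InvalidArgumentError):
            area_ratio(1.0, 0.0)


class TestAAR:
    def test_all_perfect(self):
        assert aar([1.0, 1.0, 1.0]) == 100.0

    def test_two_of_three(self):
        assert aar([1.0, 1.04, 1.06]) == pytest.approx(200 / 3)

    def test_closed_interval_boundary(self):
        assert aar([0.95, 1.05]) == 100.0
        assert aar([0.95, 1.05], closed=False) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            aar([])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.5, 1.5), min_size=1, max_size=50),
           st.permutations(range(5)))
    def test_bounded_and_permutation_invariant(self, ars, _perm):
        v = aar(ars)
        assert 0.0 <= v <= 100.0
        rng = np.random.default_rng(0)
        assert aar(list(rng.permutation(ars))) == v

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.5, 1.5), min_size=1, max_size=50))
    def test_monotone_in_tolerance(self, ars):
        assert aar(ars, 0.02) <= aar(ars, 0.05) <= aar(ars, 0.2)


class TestCentralTendency:
    def test_median_odd_even(self):
        assert median_ar([0.9, 1.0, 1.1]) == 1.0
        assert median_ar([1.0, 1.2]) == pytest.approx(1.1)

    def test_mean_std(self):
        mean, std = mean_std_ar([1, 1, 1, 1])
        assert (mean, std) == (1.0, 0.0)
        _, std2 = mean_std_ar([1.0, 1.2])
        assert std2 == pytest.approx(np.std([1.0, 1.2], ddof=1))


class TestDeltas:
    def test_delta_aar_printed_rows(self):
        assert delta_aar(83.33, 59.03) == pytest.approx(24.30)
        assert delta_aar(60.13, 5.86) == pytest.approx(54.27)
        assert delta_aar(42.0, 42.0) == 0.0

    def test_delta_abs_bias_printed_rows(self):
        assert delta_abs_bias(1.037, 0.989) == pytest.approx(0.026)
        assert delta_abs_bias(1.205, 0.995) == pytest.approx(0.200)
        # swapped-role convention (reference = final, new = ablation)
        assert delta_abs_bias(0.989, 1.013) == pytest.approx(-0.002)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.5, 1.5), st.floats(0.5, 1.5))
    def test_zero_at_equal_and_antisymmetric(self, m1, m2):
        assert delta_abs_bias(m1, m1) == 0.0
        assert delta_abs_bias(m1, m2) == pytest.approx(-delta_abs_bias(m2, m1))


class TestDetectionPR:
    def test_perfect_single_match(self):
        g = b(10, 10, 50, 50)
        p, r = detection_pr([Detection(g, Stage.LATE, 0.9)], [g])
        assert (p, r) == (1.0, 1.0)

    def test_vacuous_conventions(self):
        g = b(10, 10, 50, 50)
        assert detection_pr([Detection(g, Stage.LATE, 0.9)], []) == (0.0, 1.0)
        assert detection_pr([], [g]) == (1.0, 0.0)
        assert detection_pr([], []) == (1.0, 1.0)

    def test_two_preds_one_gt_greedy(self):
        # hand-enumerated greedy matching: high-conf pred takes the gt,
        # the second becomes a false positive
        g = b(10, 10, 50, 50)
        close = Detection(b(11, 11, 51, 51), Stage.LATE, 0.95)   # IoU ~0.9
        overlap = Detection(b(10, 22, 50, 62), Stage.LATE, 0.80)  # IoU ~0.6
        p, r = detection_pr([overlap, close], [g])
        assert (p, r) == (0.5, 1.0)

    def test_below_threshold_not_matched(self):
        g = b(10, 10, 50, 50)
        far = Detection(b(60, 60, 90, 90), Stage.LATE, 0.99)
        assert detection_pr([far], [g]) == (0.0, 0.0)


def _records(rows):
    return pd.DataFrame(rows)


GT = _records([
    {"image_id": f"i{k}", "gt_area_um2": 100.0} for k in range(5)
])


class TestStratifiedReport:
    def make_run(self, ars, weeks, flags=None):
        rows = []
        for k, (ar, wk) in enumerate(zip(ars, weeks)):
            rows.append({
                "image_id": f"i{k}", "dataset": "syn", "week": wk, "stage": "early",
                "area_um2": None if ar is None else 100.0 * ar,
                "flags": flags[k] if flags else "",
            })
        return _records(rows)

    def test_stratum_cardinality(self):
        run = self.make_run([1.0, 1.0, 1.0, 1.0, 1.0], [0, 0, 0, 4, 4])
        rep = stratified_report(run, GT)
        assert list(rep["n"]) == [3, 2]

    def test_perfect_stratum_stats(self):
        run = self.make_run([1.0] * 5, [0] * 5)
        rep = stratified_report(run, GT)
        row = rep.iloc[0]
        assert (row["aar"], row["mar"], row["std_ar"]) == (100.0, 1.0, 0.0)

    def test_failed_records_excluded_but_counted(self):
        run = self.make_run([1.0, 1.0, None, 1.0, 1.0], [0] * 5)
        rep = stratified_report(run, GT)
        assert (rep.iloc[0]["n"], rep.iloc[0]["excluded_n"]) == (4, 1)

    def test_delta_columns_match_pairwise_deltas(self):
        ref = self.make_run([1.10, 1.10, 1.04, 1.0, 1.0], [0, 0, 0, 4, 4])
        new = self.make_run([1.0, 1.0, 1.04, 0.9, 1.0], [0, 0, 0, 4, 4])
        rep = compare_runs(ref, new, GT)
        rep_ref = stratified_report(ref, GT)
        rep_new = stratified_report(new, GT)
        for i in range(len(rep)):
            assert rep.iloc[i]["delta_aar"] == pytest.approx(
                delta_aar(rep_new.iloc[i]["aar"], rep_ref.iloc[i]["aar"]))
            assert rep.iloc[i]["delta_abs_bias"] == pytest.approx(
                delta_abs_bias(rep_ref.iloc[i]["mar"], rep_new.iloc[i]["mar"]))

    def test_unmatched_id_raises_join_error(self):
        run = self.make_run([1.0] * 5, [0] * 5)
        run.loc[0, "image_id"] = "stranger"
        with pytest.raises(JoinError) as err:
            stratified_report(run, GT)
        assert "stranger" in err.value.offenders

    def test_mismatched_runs_rejected(self):
        ref = self.make_run([1.0] * 5, [0] * 5)
        new = self.make_run([1.0] * 5, [0] * 5).iloc[1:]
        with pytest.raises(JoinError):
            compare_runs(ref, new, GT)
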