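"""Evaluation engine: IoU, greedy matching, AP, report and comparison arithmetic."""

import numpy as np
import pytest

from focalaug import (
    Detection,
    EvalReport,
    IOU_GRID,
    NormBox,
    average_precision,
    class_pr_curve,
    compare_runs,
    comparison_table_csv,
    evaluate,
    f1_confidence_curve,
    iou,
    match_detections,
    pr_at_max_f1,
    pr_curve,
    relative_change,
    relative_change_value,
)
from focalaug.detect_eval import PRCurve
from focalaug.errors import ConfigError, EvaluationError

from oracles import brute_force_ap


def det(cls, conf, cx, cy, w, h):
    return Detection(cls, conf, NormBox(cls, cx, cy, w, h))


def square(cx, cy, side, cls=0):
    return NormBox(cls, cx, cy, side, side)


class TestIoU:
    def test_identical_boxes(self):
        b = square(0.5, 0.5, 0.4)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(square(0.2, 0.2, 0.1), square(0.8, 0.8, 0.1)) == 0.0

    def test_quarter_overlap(self):
        # 10x10 squares offset by (5, 5): intersection 25, union 175
        a = square(0.25, 0.25, 0.5)
        b = square(0.5, 0.5, 0.5)
        assert iou(a, b) == pytest.approx(25 / 175, abs=1e-12)

    def test_against_grid_enumeration(self, rng):
        for _ in range(50):
            wa, ha, wb, hb = rng.uniform(0.1, 0.4, size=4)
            a = NormBox(0, rng.uniform(wa / 2, 1 - wa / 2), rng.uniform(ha / 2, 1 - ha / 2), wa, ha)
            b = NormBox(0, rng.uniform(wb / 2, 1 - wb / 2), rng.uniform(hb / 2, 1 - hb / 2), wb, hb)
            n = 400
            xs = (np.arange(n) + 0.5) / n
            gx, gy = np.meshgrid(xs, xs)
            in_a = (gx > a.x1) & (gx < a.x2) & (gy > a.y1) & (gy < a.y2)
            in_b = (gx > b.x1) & (gx < b.x2) & (gy > b.y1) & (gy < b.y2)
            union = (in_a | in_b).sum()
            if union == 0:
                continue
            assert iou(a, b) == pytest.approx((in_a & in_b).sum() / union, abs=0.02)


class TestMatching:
    def test_no_ground_truth_all_fp(self):
        dets = [det(0, 0.9, 0.5, 0.5, 0.2, 0.2)]
        assert match_detections(dets, [], 0.5).tolist() == [False]

    def test_exact_hit_is_tp(self):
        gt = square(0.5, 0.5, 0.2)
        assert match_detections([det(0, 0.9, 0.5, 0.5, 0.2, 0.2)], [gt], 0.5).tolist() == [True]

    def test_duplicate_detections_second_is_fp(self):
        gt = square(0.5, 0.5, 0.2)
        dets = [det(0, 0.9, 0.5, 0.5, 0.2, 0.2), det(0, 0.8, 0.5, 0.5, 0.2, 0.2)]
        assert match_detections(dets, [gt], 0.5).tolist() == [True, False]

    def test_class_strict(self):
        gt = square(0.5, 0.5, 0.2, cls=1)
        assert match_detections([det(0, 0.9, 0.5, 0.5, 0.2, 0.2)], [gt], 0.5).tolist() == [False]

    def test_flags_follow_input_order_not_confidence_order(self):
        gt = square(0.5, 0.5, 0.2)
        dets = [det(0, 0.7, 0.5, 0.5, 0.2, 0.2), det(0, 0.9, 0.1, 0.1, 0.1, 0.1)]
        # the higher-confidence detection is off target; the lower one wins the gt
        assert match_detections(dets, [gt], 0.5).tolist() == [True, False]


def random_instance(rng):
    """A small random scene: <=5 gts, <=10 dets with distinct confidences."""
    n_gt = int(rng.integers(1, 6))
    gts = []
    for _ in range(n_gt):
        s = rng.uniform(0.08, 0.25)
        gts.append(NormBox(0, rng.uniform(s / 2, 1 - s / 2), rng.uniform(s / 2, 1 - s / 2), s, s))
    n_det = int(rng.integers(0, 11))
    confs = rng.permutation(np.linspace(0.05, 0.95, n_det)) if n_det else []
    dets = []
    for conf in confs:
        if rng.random() < 0.6 and gts:
            base = gts[int(rng.integers(len(gts)))]
            cx = float(np.clip(base.cx + rng.normal(0, 0.3 * base.w), base.w / 2, 1 - base.w / 2))
            cy = float(np.clip(base.cy + rng.normal(0, 0.3 * base.h), base.h / 2, 1 - base.h / 2))
            dets.append(det(0, float(conf), cx, cy, base.w, base.h))
        else:
            s = rng.uniform(0.05, 0.2)
            dets.append(det(0, float(conf), rng.uniform(s / 2, 1 - s / 2),
                            rng.uniform(s / 2, 1 - s / 2), s, s))
    return dets, gts


class TestAveragePrecision:
    def test_single_perfect_detection(self):
        assert average_precision([True], [0.9], 1) == 1.0

    def test_all_false_positives(self):
        assert average_precision([False, False], [0.9, 0.8], 2) == 0.0

    def test_worked_three_detection_case(self):
        # envelope: precision 1 up to recall 0.5, then 2/3 -> (51 + 50*2/3)/101
        ap = average_precision([True, False, True], [0.9, 0.8, 0.7], 2)
        assert ap == pytest.approx((51 + 50 * 2 / 3) / 101, abs=1e-12)
        assert ap == pytest.approx(0.8350, abs=5e-4)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(0, 12))
            flags = rng.random(n) < 0.5
            confs = rng.permutation(np.linspace(0.05, 0.95, n)) if n else np.zeros(0)
            n_gt = int(rng.integers(max(1, flags.sum()), max(2, flags.sum() + 4)))
            got = average_precision(flags, confs, n_gt)
            assert got == pytest.approx(brute_force_ap(list(flags), list(confs), n_gt), abs=1e-12)

    def test_nonincreasing_in_iou_threshold(self, rng):
        for _ in range(100):
            dets, gts = random_instance(rng)
            confs = [d.confidence for d in dets]
            last = 1.1
            for thr in IOU_GRID:
                flags = match_detections(dets, gts, thr)
                ap = average_precision(flags, confs, len(gts))
                assert ap <= last + 1e-12
                last = ap

    def test_permutation_of_input_order_is_safe(self, rng):
        dets, gts = random_instance(rng)
        while not dets:
            dets, gts = random_instance(rng)
        confs = [d.confidence for d in dets]
        flags = match_detections(dets, gts, 0.5)
        base = average_precision(flags, confs, len(gts))
        perm = rng.permutation(len(dets))
        dets2 = [dets[i] for i in perm]
        flags2 = match_detections(dets2, gts, 0.5)
        assert average_precision(flags2, [d.confidence for d in dets2], len(gts)) \
            == pytest.approx(base, abs=1e-12)


class TestEvaluate:
    def test_perfect_detections_give_unit_map(self):
        gts = {
            "a": [square(0.3, 0.3, 0.2, cls=0), square(0.7, 0.7, 0.1, cls=1)],
            "b": [square(0.5, 0.5, 0.3, cls=0)],
        }
        dets = {
            img: [Detection(b.class_id, 1.0, b) for b in boxes]
            for img, boxes in gts.items()
        }
        report = evaluate(dets, gts)
        assert report.map50 == 1.0 and report.map50_95 == 1.0
        for m in report.per_class:
            assert m.precision == 1.0 and m.recall == 1.0

    def test_overlap_between_first_two_thresholds(self):
        # identical squares, side s, shifted so IoU = (s-d)/(s+d) = 0.52:
        # TP at threshold 0.50 only -> AP50 = 1, higher thresholds 0
        s = 0.2
        d = s * (1 - 0.52) / (1 + 0.52)
        gts = {"a": [square(0.4, 0.5, s)]}
        dets = {"a": [det(0, 0.9, 0.4 + d, 0.5, s, s)]}
        report = evaluate(dets, gts)
        m = report.per_class[0]
        assert 0.50 < iou(dets["a"][0].box, gts["a"][0]) < 0.55
        assert m.ap_by_iou[0.5] == 1.0
        assert all(m.ap_by_iou[t] == 0.0 for t in IOU_GRID[1:])
        assert report.map50_95 == pytest.approx(0.10, abs=1e-12)

    def test_no_detections_conventions(self):
        gts = {"a": [square(0.5, 0.5, 0.2)]}
        report = evaluate({}, gts)
        m = report.per_class[0]
        assert m.precision == 0.0 and m.recall == 0.0
        assert report.map50 == 0.0 and report.map50_95 == 0.0

    def test_unknown_image_id_rejected(self):
        gts = {"a": [square(0.5, 0.5, 0.2)]}
        dets = {"zz": [det(0, 0.9, 0.5, 0.5, 0.2, 0.2)]}
        with pytest.raises(EvaluationError):
            evaluate(dets, gts)

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(EvaluationError):
            evaluate({}, {"a": []})

    def test_matching_never_crosses_images(self):
        # detection on image "b" cannot claim the ground truth on image "a"
        gts = {"a": [square(0.5, 0.5, 0.2)], "b": []}
        dets = {"b": [det(0, 0.9, 0.5, 0.5, 0.2, 0.2)]}
        report = evaluate(dets, gts)
        assert report.per_class[0].ap50 == 0.0

    def test_report_json_round_trip(self, tmp_path):
        gts = {"a": [square(0.5, 0.5, 0.2)]}
        dets = {"a": [det(0, 0.9, 0.5, 0.5, 0.2, 0.2)]}
        report = evaluate(dets, gts)
        path = tmp_path / "report.json"
        report.to_json(path)
        back = EvalReport.from_json(path)
        assert back.map50 == report.map50
        assert back.per_class[0].ap_by_iou == report.per_class[0].ap_by_iou


class TestF1Curves:
    def test_single_perfect_detection_point(self):
        curve = pr_curve([True], [0.73], 1)
        assert pr_at_max_f1(curve) == (1.0, 1.0, 0.73)

    def test_all_fp_returns_highest_confidence_point(self):
        curve = pr_curve([False, False], [0.9, 0.4], 3)
        p, r, conf = pr_at_max_f1(curve)
        assert (p, r) == (0.0, 0.0) and conf == 0.9

    def test_interior_maximum_selected(self):
        curve = PRCurve([0.9, 0.8, 0.7], [1.0, 0.8, 0.46], [1 / 3, 0.8, 0.9], n_gt=10)
        p, r, conf = pr_at_max_f1(curve)
        assert conf == 0.8 and (p, r) == (0.8, 0.8)

    def test_grid_above_all_confidences_gives_zero(self):
        curve = pr_curve([True], [0.5], 1)
        assert f1_confidence_curve(curve, [0.9]) == [(0.9, 0.0)]

    def test_perfect_detector_at_zero_threshold(self):
        curve = pr_curve([True, True], [0.9, 0.8], 2)
        assert f1_confidence_curve(curve, [0.0]) == [(0.0, 1.0)]

    def test_curve_maximum_consistent_with_operating_point(self, rng):
        dets, gts = random_instance(rng)
        while not dets:
            dets, gts = random_instance(rng)
        curve = class_pr_curve({"a": dets}, {"a": gts}, 0)
        p, r, conf = pr_at_max_f1(curve)
        best = 0.0 if p + r == 0 else 2 * p * r / (p + r)
        series = f1_confidence_curve(curve, np.linspace(0, 1, 201))
        assert max(f1 for _, f1 in series) == pytest.approx(best, abs=1e-12)


class TestComparisonArithmetic:
    def test_published_nano_row(self):
        assert relative_change(0.921, 0.912) == "+0.99%"

    def test_no_change(self):
        assert relative_change(0.5, 0.5) == "+0.00%"

    def test_halving(self):
        assert relative_change(0.5, 1.0) == "-50.00%"

    def test_zero_baseline_rejected(self):
        with pytest.raises(ConfigError):
            relative_change(0.5, 0.0)

    def test_value_form(self):
        assert relative_change_value(0.921, 0.912) == pytest.approx(0.99, abs=1e-9)

    def _report(self, map50, map50_95, pr):
        from focalaug.detect_eval import ClassMetrics

        per_class = [
            ClassMetrics(cid, p, r, {0.5: map50}, map50, map50_95) for cid, (p, r) in pr.items()
        ]
        return EvalReport(per_class, map50, map50_95)

    def test_identical_reports_all_zero_change(self):
        rep = self._report(0.9, 0.6, {0: (0.95, 0.97), 1: (0.85, 0.80)})
        rows = compare_runs(rep, rep)
        assert all(r.percent_change == "+0.00%" for r in rows)

    def test_two_class_layout_has_six_rows(self):
        a = self._report(0.921, 0.574, {0: (0.942, 0.979), 1: (0.853, 0.800)})
        b = self._report(0.912, 0.568, {0: (0.937, 0.978), 1: (0.816, 0.796)})
        rows = compare_runs(a, b)
        assert len(rows) == 6
        assert rows[0].metric == "mAP50" and rows[0].percent_change == "+0.99%"
        csv_text = comparison_table_csv(rows)
        assert csv_text.count("\n") == 7  # header + 6 rows

    def test_class_set_mismatch_rejected(self):
        a = self._report(0.9, 0.6, {0: (0.9, 0.9)})
        b = self._report(0.9, 0.6, {0: (0.9, 0.9), 1: (0.8, 0.8)})
        with pytest.raises(EvaluationError):
            compare_runs(a, b)
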