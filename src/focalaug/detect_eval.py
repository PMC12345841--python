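"""Detector evaluation from scratch.

Greedy IoU matching, 101-point interpolated average precision, mAP@50 and
mAP@50-95 (IoU thresholds 0.50:0.05:0.95), precision/recall at the max-F1
confidence, F1-confidence curves, and the percent-change comparison tables
used to contrast two augmentation runs.

Conventions: matching is class-strict and greedy in descending confidence
(ties by input order), each ground truth matches at most once; AP uses the
COCO-style precision envelope averaged at the 101 recall points 0, 0.01,
..., 1.00; a class with predictions but no ground truth is excluded from
macro means; precision with no predictions is 0.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .detdata import NormBox, parse_label_file
from .errors import ConfigError, EvaluationError, LabelParseError

#: the mAP@50-95 threshold grid: 0.50, 0.55, ..., 0.95.
IOU_GRID: tuple[float, ...] = tuple(round(0.5 + 0.05 * i, 2) for i in range(10))
#: the 101 recall points of the interpolated AP.
RECALL_GRID: np.ndarray = np.arange(101) / 100.0


@dataclass(frozen=True)
class Detection:
    """A confidence-scored predicted box."""

    class_id: int
    confidence: float
    box: NormBox

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ConfigError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass
class PRCurve:
    """Precision/recall swept over descending confidence thresholds."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    n_gt: int

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        self.precision = np.asarray(self.precision, dtype=np.float64)
        self.recall = np.asarray(self.recall, dtype=np.float64)
        if not (len(self.thresholds) == len(self.precision) == len(self.recall)):
            raise EvaluationError("curve arrays must be aligned")
        if self.n_gt < 1:
            raise EvaluationError(f"n_gt must be >= 1, got {self.n_gt}")


@dataclass
class ClassMetrics:
    """Per-class summary: AP per IoU threshold plus the max-F1 operating point."""

    class_id: int
    precision: float
    recall: float
    ap_by_iou: dict[float, float]
    ap50: float
    ap50_95: float


@dataclass
class EvalReport:
    """Per-class metrics plus macro means across classes present in ground truth."""

    per_class: list[ClassMetrics]
    map50: float
    map50_95: float

    def to_dict(self) -> dict:
        return {
            "map50": self.map50,
            "map50_95": self.map50_95,
            "per_class": [
                {
                    "class_id": m.class_id,
                    "precision": m.precision,
                    "recall": m.recall,
                    "ap50": m.ap50,
                    "ap50_95": m.ap50_95,
                    "ap_by_iou": {f"{t:.2f}": v for t, v in m.ap_by_iou.items()},
                }
                for m in self.per_class
            ],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "EvalReport":
        per_class = [
            ClassMetrics(
                class_id=int(m["class_id"]),
                precision=float(m["precision"]),
                recall=float(m["recall"]),
                ap_by_iou={float(t): float(v) for t, v in m["ap_by_iou"].items()},
                ap50=float(m["ap50"]),
                ap50_95=float(m["ap50_95"]),
            )
            for m in d["per_class"]
        ]
        return cls(per_class, float(d["map50"]), float(d["map50_95"]))

    @classmethod
    def from_json(cls, path: str | Path) -> "EvalReport":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass(frozen=True)
class ComparisonRow:
    """One line of the two-run comparison table."""

    label: str
    metric: str
    value_a: float
    value_b: float
    percent_change: str


# ---------------------------------------------------------------------------
# geometry and matching


def iou(a: NormBox, b: NormBox) -> float:
    """Intersection over union of two boxes in continuous coordinates."""
    ix = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = ix * iy
    if inter == 0.0:
        return 0.0
    # areas from the same edge coordinates as the intersection, so that
    # identical boxes give exactly 1.0
    area_a = (a.x2 - a.x1) * (a.y2 - a.y1)
    area_b = (b.x2 - b.x1) * (b.y2 - b.y1)
    return inter / (area_a + area_b - inter)


def match_detections(
    dets: Sequence[Detection], gts: Sequence[NormBox], iou_thr: float
) -> np.ndarray:
    """Greedy one-to-one TP/FP assignment, returned in the input det order.

    Detections are visited in descending confidence (ties by input order);
    a detection is a TP if its best-IoU unmatched same-class ground truth
    reaches ``iou_thr``, which then becomes matched.
    """
    flags = np.zeros(len(dets), dtype=bool)
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    matched = [False] * len(gts)
    for i in order:
        det = dets[i]
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gts):
            if matched[j] or gt.class_id != det.class_id:
                continue
            v = iou(det.box, gt)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_thr:
            flags[i] = True
            matched[best_j] = True
    return flags


# ---------------------------------------------------------------------------
# precision/recall and AP


def _sorted_flags(flags: np.ndarray, confidences: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(-np.asarray(confidences, dtype=np.float64), kind="stable")
    return np.asarray(flags, dtype=bool)[order], np.asarray(confidences, dtype=np.float64)[order]


def pr_curve(flags: Sequence[bool], confidences: Sequence[float], n_gt: int) -> PRCurve:
    """Cumulative precision/recall over descending confidence."""
    if n_gt < 1:
        raise EvaluationError(f"n_gt must be >= 1, got {n_gt}")
    f, c = _sorted_flags(np.asarray(flags), np.asarray(confidences))
    tp = np.cumsum(f)
    k = np.arange(1, len(f) + 1)
    return PRCurve(thresholds=c, precision=tp / k, recall=tp / n_gt, n_gt=n_gt)


def average_precision(
    flags: Sequence[bool], confidences: Sequence[float], n_gt: int
) -> float:
    """101-point interpolated AP.

    The precision envelope (max precision at recall >= r) is averaged over
    the recall grid {0, 0.01, ..., 1.00}.
    """
    if n_gt < 1:
        raise EvaluationError(f"n_gt must be >= 1, got {n_gt}")
    f, _ = _sorted_flags(np.asarray(flags), np.asarray(confidences))
    if len(f) == 0:
        return 0.0
    tp = np.cumsum(f)
    prec = tp / np.arange(1, len(f) + 1)
    rec = tp / n_gt
    envelope = np.maximum.accumulate(prec[::-1])[::-1]
    idx = np.searchsorted(rec, RECALL_GRID, side="left")
    values = np.where(idx < len(f), envelope[np.minimum(idx, len(f) - 1)], 0.0)
    return float(values.sum() / len(RECALL_GRID))


def pr_at_max_f1(curve: PRCurve) -> tuple[float, float, float]:
    """The (precision, recall, confidence) point maximizing F1 = 2PR/(P+R).

    Ties are broken toward higher confidence (the curve is stored in
    descending-confidence order, so the first maximum wins).
    """
    if len(curve.thresholds) == 0:
        raise EvaluationError("empty curve")
    p, r = curve.precision, curve.recall
    denom = p + r
    f1 = np.divide(2 * p * r, denom, out=np.zeros_like(denom), where=denom > 0)
    i = int(np.argmax(f1))
    return float(p[i]), float(r[i]), float(curve.thresholds[i])


def f1_confidence_curve(
    curve: PRCurve, grid: Sequence[float]
) -> list[tuple[float, float]]:
    """F1 at each grid confidence, keeping detections with conf >= that value."""
    out: list[tuple[float, float]] = []
    neg_thr = -curve.thresholds  # ascending
    for g in grid:
        if not 0.0 <= g <= 1.0:
            raise ConfigError(f"grid confidence {g} outside [0, 1]")
        count = int(np.searchsorted(neg_thr, -g, side="right"))
        if count == 0:
            out.append((float(g), 0.0))
            continue
        p, r = curve.precision[count - 1], curve.recall[count - 1]
        f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
        out.append((float(g), float(f1)))
    return out


# ---------------------------------------------------------------------------
# full evaluation


def evaluate(
    dets_by_image: Mapping[str, Sequence[Detection]],
    gts_by_image: Mapping[str, Sequence[NormBox]],
    iou_thresholds: Sequence[float] = IOU_GRID,
) -> EvalReport:
    """Pool per-image matches per class/threshold and summarize.

    For each class and each IoU threshold, TP/FP flags are computed per
    image (matching never crosses images), pooled, and swept into a PR
    curve; AP@50-95 averages AP over the grid. Scalar precision/recall are
    read at the max-F1 confidence of the IoU-0.50 curve. Macro means run
    over classes present in the ground truth.
    """
    unknown = set(dets_by_image) - set(gts_by_image)
    if unknown:
        raise EvaluationError(f"detections reference unknown image ids: {sorted(unknown)[:5]}")
    classes = sorted({b.class_id for boxes in gts_by_image.values() for b in boxes})
    if not classes:
        raise EvaluationError("ground truth collection is empty")
    iou_thresholds = tuple(float(t) for t in iou_thresholds)

    per_class: list[ClassMetrics] = []
    for cls_id in classes:
        n_gt = sum(1 for boxes in gts_by_image.values() for b in boxes if b.class_id == cls_id)
        ap_by_iou: dict[float, float] = {}
        curve50: PRCurve | None = None
        for thr in iou_thresholds:
            flags_all: list[np.ndarray] = []
            confs_all: list[np.ndarray] = []
            for image_id, gts in gts_by_image.items():
                dets = [d for d in dets_by_image.get(image_id, ()) if d.class_id == cls_id]
                gtc = [b for b in gts if b.class_id == cls_id]
                if not dets:
                    continue
                flags_all.append(match_detections(dets, gtc, thr))
                confs_all.append(np.array([d.confidence for d in dets]))
            flags = np.concatenate(flags_all) if flags_all else np.zeros(0, dtype=bool)
            confs = np.concatenate(confs_all) if confs_all else np.zeros(0)
            ap_by_iou[thr] = average_precision(flags, confs, n_gt)
            if math.isclose(thr, 0.5) and len(flags):
                curve50 = pr_curve(flags, confs, n_gt)
        if curve50 is not None:
            precision, recall, _ = pr_at_max_f1(curve50)
        else:
            precision, recall = 0.0, 0.0  # no predictions for this class
        ap50 = ap_by_iou.get(0.5, ap_by_iou[iou_thresholds[0]])
        ap50_95 = float(np.mean([ap_by_iou[t] for t in iou_thresholds]))
        per_class.append(
            ClassMetrics(cls_id, precision, recall, ap_by_iou, ap50, ap50_95)
        )
    map50 = float(np.mean([m.ap50 for m in per_class]))
    map50_95 = float(np.mean([m.ap50_95 for m in per_class]))
    return EvalReport(per_class, map50, map50_95)


def class_pr_curve(
    dets_by_image: Mapping[str, Sequence[Detection]],
    gts_by_image: Mapping[str, Sequence[NormBox]],
    class_id: int,
    iou_thr: float = 0.5,
) -> PRCurve:
    """The pooled PR curve of one class at one IoU threshold."""
    flags_all: list[np.ndarray] = []
    confs_all: list[np.ndarray] = []
    n_gt = 0
    for image_id, gts in gts_by_image.items():
        gtc = [b for b in gts if b.class_id == class_id]
        n_gt += len(gtc)
        dets = [d for d in dets_by_image.get(image_id, ()) if d.class_id == class_id]
        if not dets:
            continue
        flags_all.append(match_detections(dets, gtc, iou_thr))
        confs_all.append(np.array([d.confidence for d in dets]))
    if n_gt == 0:
        raise EvaluationError(f"no ground truths of class {class_id}")
    flags = np.concatenate(flags_all) if flags_all else np.zeros(0, dtype=bool)
    confs = np.concatenate(confs_all) if confs_all else np.zeros(0)
    return pr_curve(flags, confs, n_gt)


# ---------------------------------------------------------------------------
# comparison arithmetic


def relative_change_value(v_new: float, v_old: float) -> float:
    """Signed percent change 100*(v_new - v_old)/v_old, rounded to 2 decimals."""
    if v_old <= 0:
        raise ConfigError(f"baseline value must be > 0, got {v_old}")
    return round(100.0 * (v_new - v_old) / v_old, 2)


def relative_change(v_new: float, v_old: float) -> str:
    """The percent change rendered with an explicit sign, e.g. ``"+0.99%"``."""
    return f"{relative_change_value(v_new, v_old):+.2f}%"


def compare_runs(
    report_a: EvalReport,
    report_b: EvalReport,
    label: str = "",
    class_names: Mapping[int, str] | None = None,
) -> list[ComparisonRow]:
    """Rows contrasting run A against baseline run B.

    Layout: two macro mAP rows, then per-class precision and recall, each
    with the signed percent change of A relative to B.
    """
    classes_a = {m.class_id for m in report_a.per_class}
    classes_b = {m.class_id for m in report_b.per_class}
    if classes_a != classes_b:
        raise EvaluationError(f"class sets differ: {sorted(classes_a)} vs {sorted(classes_b)}")
    rows = [
        ComparisonRow(label, "mAP50", report_a.map50, report_b.map50,
                      relative_change(report_a.map50, report_b.map50)),
        ComparisonRow(label, "mAP50-95", report_a.map50_95, report_b.map50_95,
                      relative_change(report_a.map50_95, report_b.map50_95)),
    ]
    by_id_b = {m.class_id: m for m in report_b.per_class}
    for ma in sorted(report_a.per_class, key=lambda m: m.class_id):
        mb = by_id_b[ma.class_id]
        name = class_names.get(ma.class_id, str(ma.class_id)) if class_names else str(ma.class_id)
        for metric in ("precision", "recall"):
            va, vb = getattr(ma, metric), getattr(mb, metric)
            rows.append(
                ComparisonRow(label, f"{metric} ({name})", va, vb, relative_change(va, vb))
            )
    return rows


def comparison_table_csv(rows: Sequence[ComparisonRow], path: str | Path | None = None) -> str:
    """Render comparison rows as CSV (header + one line per row)."""
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["label", "metric", "value_a", "value_b", "percent_change"])
    for r in rows:
        writer.writerow([r.label, r.metric, f"{r.value_a:.6f}", f"{r.value_b:.6f}", r.percent_change])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# detection file I/O: one text file per image, "class conf cx cy w h"


def parse_detection_file(text: str) -> list[Detection]:
    dets: list[Detection] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        tokens = line.split()
        if len(tokens) != 6:
            raise LabelParseError(f"line {lineno}: expected 6 tokens, got {len(tokens)}")
        try:
            class_id = int(tokens[0])
            conf = float(tokens[1])
            cx, cy, w, h = (float(t) for t in tokens[2:])
        except ValueError as exc:
            raise LabelParseError(f"line {lineno}: non-numeric token ({exc})") from exc
        dets.append(Detection(class_id, conf, NormBox(class_id, cx, cy, w, h)))
    return dets


def write_detection_file(dets: Sequence[Detection]) -> str:
    return "".join(
        f"{d.class_id} {d.confidence:.6f} {d.box.cx:.6f} {d.box.cy:.6f} "
        f"{d.box.w:.6f} {d.box.h:.6f}\n"
        for d in dets
    )


def load_detections(directory: str | Path) -> dict[str, list[Detection]]:
    """Read every ``*.txt`` in a directory as per-image detections."""
    directory = Path(directory)
    out: dict[str, list[Detection]] = {}
    for path in sorted(directory.glob("*.txt")):
        out[path.stem] = parse_detection_file(path.read_text(encoding="utf-8"))
    return out


def save_detections(dets_by_image: Mapping[str, Sequence[Detection]], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for image_id, dets in dets_by_image.items():
        (directory / f"{image_id}.txt").write_text(write_detection_file(dets), encoding="utf-8")
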