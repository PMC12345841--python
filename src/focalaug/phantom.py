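"""Synthetic CT-like rib phantoms and a simulated imperfect detector.

The phantom is schematic, not anatomical: a dark noisy background crossed
by bright, gently curved horizontal bands standing in for rib
cross-sections. A band may carry a darkened gap (a "fracture" defect),
tightly boxed as class 1; intact band segments are boxed as class 0, and
are more numerous in expectation, mirroring the class imbalance of real
fracture datasets. All outputs are integer-valued and deterministic under
a fixed seed.

The detector simulator is a test double for a trained model: it emits each
ground truth with probability 1 - miss_rate (optionally jittered), plus
Poisson-distributed false positives, with TP confidences drawn above FP
confidences so precision-recall sweeps are non-degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .detdata import (
    DetDataset,
    ImageGrid,
    LabeledImage,
    NormBox,
    split_dataset,
)
from .detect_eval import Detection
from .errors import ConfigError
from ._rng import rng_for

CLASS_NAMES = {0: "no_fracture", 1: "fracture"}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and noise of the generated phantoms.

    image_size is the square frame edge in pixels (640 matches the study
    resolution; tests use smaller frames). fracture_prob_per_band is the
    chance a rib band carries a gap defect; with 1-2 intact segments boxed
    per band, class-0 boxes outnumber class-1 boxes in expectation.
    """

    image_size: int = 640
    n_rib_bands: int = 8
    fracture_prob_per_band: float = 0.3
    background_noise_std: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ConfigError(f"image_size must be >= 64, got {self.image_size}")
        if self.n_rib_bands < 1:
            raise ConfigError(f"n_rib_bands must be >= 1, got {self.n_rib_bands}")
        if not 0 <= self.fracture_prob_per_band <= 1:
            raise ConfigError(f"fracture_prob_per_band must be in [0, 1]")
        if self.background_noise_std < 0:
            raise ConfigError("background_noise_std must be >= 0")


@dataclass(frozen=True)
class DetectorSimConfig:
    """Error model of the simulated detector."""

    miss_rate: float = 0.1
    fp_per_image: float = 0.5
    loc_jitter_std: float = 0.0
    tp_conf_range: tuple[float, float] = (0.60, 0.95)
    fp_conf_range: tuple[float, float] = (0.05, 0.45)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.miss_rate <= 1:
            raise ConfigError(f"miss_rate must be in [0, 1], got {self.miss_rate}")
        if self.fp_per_image < 0:
            raise ConfigError("fp_per_image must be >= 0")
        if self.loc_jitter_std < 0:
            raise ConfigError("loc_jitter_std must be >= 0")
        for name, (lo, hi) in (("tp_conf_range", self.tp_conf_range),
                               ("fp_conf_range", self.fp_conf_range)):
            if not (0 <= lo <= hi <= 1):
                raise ConfigError(f"{name} must satisfy 0 <= lo <= hi <= 1")
        if self.tp_conf_range[0] < self.fp_conf_range[1]:
            raise ConfigError("tp_conf_range must lie above fp_conf_range")


def _box_from_pixels(class_id: int, x1: float, y1: float, x2: float, y2: float,
                     S: int) -> NormBox:
    x1, y1 = max(0.0, x1), max(0.0, y1)
    x2, y2 = min(float(S), x2), min(float(S), y2)
    return NormBox(class_id, (x1 + x2) / 2 / S, (y1 + y2) / 2 / S,
                   (x2 - x1) / S, (y2 - y1) / S)


def generate_phantom(
    config: PhantomConfig, rng: np.random.Generator, image_id: str = "phantom"
) -> LabeledImage:
    """One labeled phantom frame.

    The defect gap inside every class-1 box is darkened toward background
    level, so its mean intensity sits well below the surrounding band — a
    contrast cue detectors (and tests) can rely on.
    """
    S = config.image_size
    img = 18.0 + rng.normal(0.0, config.background_noise_std, (S, S))

    x = np.arange(S)
    u = (x - S / 2.0) / (S / 2.0)  # [-1, 1] across the frame
    boxes: list[NormBox] = []
    band_top, band_bot = 0.10 * S, 0.88 * S
    centers = np.linspace(band_top, band_bot, config.n_rib_bands)
    thickness = max(3, round(0.018 * S))
    margin = 2  # label boxes include this many pixels of intact band

    for y0 in centers:
        sag = rng.uniform(0.015, 0.045) * S
        intensity = rng.uniform(170.0, 220.0)
        yc = y0 + sag * u**2  # per-column band center (a shallow arc)
        lo = np.clip(np.round(yc - thickness / 2).astype(int), 0, S - 1)
        hi = np.clip(lo + thickness, 1, S)
        for xi in range(S):
            img[lo[xi]:hi[xi], xi] = intensity + rng.normal(0.0, 3.0, hi[xi] - lo[xi])

        gap_span: tuple[int, int] | None = None
        if rng.random() < config.fracture_prob_per_band:
            gap_w = max(4, round(rng.uniform(0.020, 0.040) * S))
            gx1 = int(rng.integers(round(0.15 * S), round(0.85 * S) - gap_w))
            gx2 = gx1 + gap_w
            gap_level = rng.uniform(22.0, 38.0)
            for xi in range(gx1, gx2):
                img[lo[xi]:hi[xi], xi] = gap_level + rng.normal(0.0, 2.0, hi[xi] - lo[xi])
            gap_span = (gx1, gx2)
            boxes.append(_box_from_pixels(
                1, gx1 - margin, lo[gx1:gx2].min() - margin,
                gx2 + margin, hi[gx1:gx2].max() + margin, S))

        n_intact = int(rng.integers(1, 3))  # 1 or 2 intact segments boxed
        for _ in range(n_intact):
            seg_w = max(6, round(rng.uniform(0.04, 0.08) * S))
            for _attempt in range(8):
                sx1 = int(rng.integers(round(0.05 * S), round(0.95 * S) - seg_w))
                sx2 = sx1 + seg_w
                if gap_span is None or sx2 <= gap_span[0] - margin or sx1 >= gap_span[1] + margin:
                    boxes.append(_box_from_pixels(
                        0, sx1, lo[sx1:sx2].min() - margin,
                        sx2, hi[sx1:sx2].max() + margin, S))
                    break

    return LabeledImage(image_id, ImageGrid(np.floor(np.clip(img, 0, 255) + 0.5)
                                            .astype(np.uint8)[:, :, None]), tuple(boxes))


def generate_dataset(n_images: int, config: PhantomConfig) -> DetDataset:
    """n phantoms with sequential ids, split 70/20/10."""
    if n_images < 1:
        raise ConfigError(f"n_images must be >= 1, got {n_images}")
    items = [
        generate_phantom(config, rng_for(config.seed, f"phantom_{i:05d}"), f"phantom_{i:05d}")
        for i in range(n_images)
    ]
    train, val, test = split_dataset(items, (0.7, 0.2, 0.1), seed=config.seed)
    return DetDataset(class_names=dict(CLASS_NAMES),
                      splits={"train": train, "val": val, "test": test})


def simulate_detections(
    gts_by_image: Mapping[str, Sequence[NormBox]], sim: DetectorSimConfig
) -> dict[str, list[Detection]]:
    """Emit noisy detections for every image's ground truths.

    Each ground truth survives with probability 1 - miss_rate; surviving
    boxes get center/size jitter scaled by loc_jitter_std (a fraction of
    the box extent) and a confidence uniform in tp_conf_range. False
    positives arrive Poisson(fp_per_image) per image, placed uniformly
    with confidences in fp_conf_range.
    """
    classes = sorted({b.class_id for boxes in gts_by_image.values() for b in boxes}) or [0, 1]
    out: dict[str, list[Detection]] = {}
    for image_id in sorted(gts_by_image):
        rng = rng_for(sim.seed, image_id, "simdet")
        dets: list[Detection] = []
        for gt in gts_by_image[image_id]:
            if rng.random() < sim.miss_rate:
                continue
            j = sim.loc_jitter_std
            cx = gt.cx + rng.normal(0.0, j * gt.w) if j else gt.cx
            cy = gt.cy + rng.normal(0.0, j * gt.h) if j else gt.cy
            w = gt.w * max(0.2, 1.0 + rng.normal(0.0, j)) if j else gt.w
            h = gt.h * max(0.2, 1.0 + rng.normal(0.0, j)) if j else gt.h
            w, h = min(w, 1.0), min(h, 1.0)
            cx, cy = np.clip(cx, w / 2, 1 - w / 2), np.clip(cy, h / 2, 1 - h / 2)
            conf = float(rng.uniform(*sim.tp_conf_range))
            dets.append(Detection(gt.class_id, conf, NormBox(gt.class_id, cx, cy, w, h)))
        for _ in range(int(rng.poisson(sim.fp_per_image))):
            w, h = rng.uniform(0.03, 0.12, size=2)
            cx = rng.uniform(w / 2, 1 - w / 2)
            cy = rng.uniform(h / 2, 1 - h / 2)
            cls = int(classes[int(rng.integers(len(classes)))])
            conf = float(rng.uniform(*sim.fp_conf_range))
            dets.append(Detection(cls, conf, NormBox(cls, cx, cy, w, h)))
        out[image_id] = dets
    return out
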