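"""Conventional whole-image augmentation baseline.

The global strategy the focused operator is compared against: random
rotation within +/-30 degrees, brightness/contrast adjustment, and
whole-frame Gaussian blurring, each applied with a per-transform
probability. Rotated boxes are replaced by the axis-aligned envelope of
their exactly rotated corners, clipped to the frame, and dropped when too
little of the original area remains visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .detdata import ImageGrid, LabeledImage, NormBox
from .errors import ConfigError
from .focal_augment import RegionMask, _quantize, blur_region, make_gaussian_kernel
from ._rng import rng_for


@dataclass(frozen=True)
class GlobalAugmentConfig:
    """Ranges and probabilities of the conventional transforms.

    Rotation angle is drawn uniformly in [-max_rotation_deg,
    +max_rotation_deg]; brightness shift in +/-brightness_delta gray
    levels; contrast factor in contrast_factor_range. Each of the three
    transforms fires independently with probability p_apply; if all three
    decline, the rotation is forced so a copy is never pixel-identical.
    min_box_visibility is the fraction of a box's area that must survive
    clipping after rotation for the box to be kept.
    """

    max_rotation_deg: float = 30.0
    brightness_delta: float = 25.0
    contrast_factor_range: tuple[float, float] = (0.8, 1.2)
    blur_kernel_size: int = 3
    blur_sigma: float = 1.0
    p_apply: float = 0.5
    min_box_visibility: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.max_rotation_deg <= 90:
            raise ConfigError(f"max_rotation_deg must be in [0, 90], got {self.max_rotation_deg}")
        if not 0 <= self.p_apply <= 1:
            raise ConfigError(f"p_apply must be in [0, 1], got {self.p_apply}")
        lo, hi = self.contrast_factor_range
        if lo <= 0 or hi < lo:
            raise ConfigError(f"bad contrast_factor_range {self.contrast_factor_range}")
        if self.blur_kernel_size < 1 or self.blur_kernel_size % 2 == 0:
            raise ConfigError(f"blur_kernel_size must be odd, got {self.blur_kernel_size}")
        if not 0 <= self.min_box_visibility <= 1:
            raise ConfigError(f"min_box_visibility must be in [0, 1], got {self.min_box_visibility}")


def _rotation_matrix(angle_deg: float) -> np.ndarray:
    t = math.radians(angle_deg)
    c, s = math.cos(t), math.sin(t)
    # (x, y) with y pointing down; positive angles rotate content clockwise
    # on screen, which is immaterial as long as image and boxes agree.
    return np.array([[c, -s], [s, c]])


def rotate_image_and_boxes(
    image: ImageGrid,
    boxes: Sequence[NormBox],
    angle: float,
    min_box_visibility: float = 0.2,
) -> tuple[ImageGrid, list[NormBox]]:
    """Rotate about the frame center, keeping the canvas size.

    The raster is resampled bilinearly with out-of-frame fill 0. Each box's
    four corners are rotated exactly (continuous coordinates), replaced by
    their axis-aligned envelope, clipped to the frame, and dropped if the
    clipped area falls below ``min_box_visibility`` of the original.
    """
    if abs(angle) > 180:
        raise ConfigError(f"|angle| must be <= 180, got {angle}")
    H, W = image.height, image.width
    R = _rotation_matrix(angle)
    center = np.array([W / 2.0, H / 2.0])

    # Inverse map for resampling: output index (row, col) -> input index.
    # Continuous position of index (y, x) is (x + 1/2, y + 1/2).
    Rinv = _rotation_matrix(-angle)
    M_rc = np.array([[Rinv[1, 1], Rinv[1, 0]], [Rinv[0, 1], Rinv[0, 0]]])
    c_rc = np.array([H / 2.0, W / 2.0])
    offset = M_rc @ (0.5 - c_rc) + c_rc - 0.5
    v = image.values.astype(np.float64)
    rotated = np.empty_like(v)
    for ch in range(v.shape[2]):
        rotated[:, :, ch] = ndimage.affine_transform(
            v[:, :, ch], M_rc, offset=offset, order=1, mode="constant", cval=0.0
        )
    out_image = ImageGrid(_quantize(rotated))

    out_boxes: list[NormBox] = []
    for box in boxes:
        corners = np.array(
            [
                [box.x1 * W, box.y1 * H],
                [box.x2 * W, box.y1 * H],
                [box.x2 * W, box.y2 * H],
                [box.x1 * W, box.y2 * H],
            ]
        )
        rot = (R @ (corners - center).T).T + center
        x1, y1 = rot.min(axis=0)
        x2, y2 = rot.max(axis=0)
        cx1, cy1 = max(x1, 0.0), max(y1, 0.0)
        cx2, cy2 = min(x2, float(W)), min(y2, float(H))
        if cx2 <= cx1 or cy2 <= cy1:
            continue
        original_area = box.w * W * box.h * H
        if (cx2 - cx1) * (cy2 - cy1) < min_box_visibility * original_area:
            continue
        out_boxes.append(
            NormBox(
                box.class_id,
                (cx1 + cx2) / 2.0 / W,
                (cy1 + cy2) / 2.0 / H,
                (cx2 - cx1) / W,
                (cy2 - cy1) / H,
            )
        )
    return out_image, out_boxes


def adjust_brightness_contrast(
    image: ImageGrid, contrast: float, brightness: float
) -> ImageGrid:
    """Per-pixel ``clip(round(contrast * I + brightness), 0, 255)``."""
    if contrast <= 0:
        raise ConfigError(f"contrast must be > 0, got {contrast}")
    return ImageGrid(_quantize(contrast * image.values.astype(np.float64) + brightness))


def conventional_augment_image(
    item: LabeledImage,
    config: GlobalAugmentConfig,
    rng: np.random.Generator,
    suffix: str = "_conv",
) -> LabeledImage:
    """One globally augmented copy: rotation, photometric shift, blur.

    All random parameters are drawn up front in a fixed order so the output
    is fully determined by the generator's state. If every probability draw
    declines, the rotation is applied anyway.
    """
    angle = float(rng.uniform(-config.max_rotation_deg, config.max_rotation_deg))
    contrast = float(rng.uniform(*config.contrast_factor_range))
    brightness = float(rng.uniform(-config.brightness_delta, config.brightness_delta))
    apply = rng.random(3) < config.p_apply
    if not apply.any():
        apply[0] = True

    image, boxes = item.image, list(item.boxes)
    if apply[0]:
        image, boxes = rotate_image_and_boxes(image, boxes, angle, config.min_box_visibility)
    if apply[1]:
        image = adjust_brightness_contrast(image, contrast, brightness)
    if apply[2]:
        kernel = make_gaussian_kernel(config.blur_kernel_size, config.blur_sigma)
        full = RegionMask(np.ones((image.height, image.width), dtype=bool))
        image = blur_region(image, full, kernel)
    return LabeledImage(item.image_id + suffix, image, tuple(boxes))


def conventional_augment_set(
    train: Sequence[LabeledImage], config: GlobalAugmentConfig
) -> list[LabeledImage]:
    """Originals plus one conventional variant each (dataset doubles)."""
    if not train:
        raise ConfigError("training set must be non-empty")
    out = list(train)
    for item in train:
        rng = rng_for(config.seed, item.image_id, "conv")
        out.append(conventional_augment_image(item, config, rng))
    return out
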