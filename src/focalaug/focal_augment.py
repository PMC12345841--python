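"""Focused (region-targeted) augmentation.

The transform perturbs only the pixels inside annotated target-class
bounding boxes: multiplicative speckle noise

    I' = clip(I + I * n, 0, 255),   n ~ N(0, sigma^2)

followed by Gaussian smoothing of the same region,

    I''(x, y) = sum_{i=-k}^{k} sum_{j=-k}^{k} I'(x+i, y+j) * G(i, j)

with a normalized (2k+1)x(2k+1) Gaussian kernel. Everything outside the
box union is left bit-identical, and box geometry is untouched, so the
augmented copy reuses the original label file verbatim. Augmented copies
are merged with the originals to grow the training split.

Conventions (the formulas above leave them open): arithmetic is done in
float, rounded half-away-from-zero to integers after each stage; the blur
reads its neighborhoods from the full noise-applied image (reflect padding
at the frame border) but writes only inside the mask, so there is no seam
at box edges; one noise draw per pixel position is shared across channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .detdata import ImageGrid, LabeledImage, NormBox, to_pixel
from .errors import ConfigError, ValidationError
from ._rng import rng_for


def _quantize(values: np.ndarray) -> np.ndarray:
    """Clip to [0, 255] then round half-away-from-zero to uint8."""
    return np.floor(np.clip(values, 0.0, 255.0) + 0.5).astype(np.uint8)


@dataclass(frozen=True)
class AugmentConfig:
    """Parameters of the focused-augmentation operator.

    sigma_speckle
        Standard deviation of the unitless multiplicative noise (0.10 by
        default, i.e. ~10 gray levels at mid intensity).
    kernel_size
        Odd Gaussian window size; 5 means half-width k = 2.
    sigma_blur
        Gaussian standard deviation in pixels.
    target_classes
        Class ids whose boxes define the augmented region (default {1},
        the fracture class).
    copies_per_image
        Augmented variants generated per original.
    """

    sigma_speckle: float = 0.10
    kernel_size: int = 5
    sigma_blur: float = 1.0
    target_classes: frozenset[int] = frozenset({1})
    copies_per_image: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_speckle < 0:
            raise ConfigError(f"sigma_speckle must be >= 0, got {self.sigma_speckle}")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ConfigError(f"kernel_size must be odd and >= 1, got {self.kernel_size}")
        if self.sigma_blur < 0:
            raise ConfigError(f"sigma_blur must be >= 0, got {self.sigma_blur}")
        if not self.target_classes:
            raise ConfigError("target_classes must be non-empty")
        object.__setattr__(self, "target_classes", frozenset(int(c) for c in self.target_classes))
        if self.copies_per_image < 1:
            raise ConfigError(f"copies_per_image must be >= 1, got {self.copies_per_image}")


@dataclass(frozen=True)
class GaussianKernel:
    """Normalized, reflection-symmetric smoothing weights with half-width k."""

    weights: np.ndarray
    k: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        size = 2 * self.k + 1
        if w.shape != (size, size):
            raise ValidationError(f"kernel shape {w.shape} inconsistent with k={self.k}")
        if abs(float(w.sum()) - 1.0) > 1e-12:
            raise ValidationError("kernel weights must sum to 1")
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class RegionMask:
    """Boolean H x W flags marking where augmentation applies."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.flags)
        if f.ndim != 2 or f.dtype != np.bool_:
            raise ValidationError(f"mask must be a 2-D boolean array, got {f.dtype} {f.shape}")
        f = np.ascontiguousarray(f)
        f.setflags(write=False)
        object.__setattr__(self, "flags", f)

    @property
    def coverage(self) -> float:
        """Fraction of the frame covered by the mask."""
        return float(self.flags.mean())


def make_gaussian_kernel(kernel_size: int, sigma_blur: float) -> GaussianKernel:
    """Build the normalized (2k+1)x(2k+1) Gaussian weight matrix.

    ``sigma_blur = 0`` degenerates to the identity (delta) kernel.
    """
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ConfigError(f"kernel_size must be odd and >= 1, got {kernel_size}")
    if sigma_blur < 0:
        raise ConfigError(f"sigma_blur must be >= 0, got {sigma_blur}")
    k = kernel_size // 2
    if sigma_blur == 0:
        w = np.zeros((kernel_size, kernel_size))
        w[k, k] = 1.0
        return GaussianKernel(w, k)
    offsets = np.arange(-k, k + 1, dtype=np.float64)
    ii, jj = np.meshgrid(offsets, offsets, indexing="ij")
    w = np.exp(-(ii**2 + jj**2) / (2.0 * sigma_blur**2))
    return GaussianKernel(w / w.sum(), k)


def build_mask(
    boxes: Iterable[NormBox], target_classes: Iterable[int], W: int, H: int
) -> RegionMask:
    """Union of the pixel regions of all target-class boxes (false elsewhere)."""
    targets = set(int(c) for c in target_classes)
    flags = np.zeros((H, W), dtype=bool)
    for box in boxes:
        if box.class_id not in targets:
            continue
        p = to_pixel(box, W, H)
        flags[p.y1 : p.y2, p.x1 : p.x2] = True
    return RegionMask(flags)


def speckle_noise(
    image: ImageGrid, mask: RegionMask, sigma: float, rng: np.random.Generator
) -> ImageGrid:
    """Apply multiplicative Gaussian noise inside the mask.

    Masked pixels become ``clip(I + I*n, 0, 255)`` rounded to integers with
    one draw of ``n ~ N(0, sigma^2)`` per pixel position, shared across
    channels. Unmasked pixels are returned bit-identical.
    """
    if sigma < 0:
        raise ConfigError(f"sigma must be >= 0, got {sigma}")
    if mask.flags.shape != image.values.shape[:2]:
        raise ValidationError("mask shape does not match image")
    if sigma == 0 or not mask.flags.any():
        return ImageGrid(image.values.copy())
    noise = rng.normal(0.0, sigma, size=mask.flags.shape)
    v = image.values.astype(np.float64)
    noisy = _quantize(v * (1.0 + noise[:, :, None]))
    out = image.values.copy()
    out[mask.flags] = noisy[mask.flags]
    return ImageGrid(out)


def blur_region(image: ImageGrid, mask: RegionMask, kernel: GaussianKernel) -> ImageGrid:
    """Gaussian-smooth the masked pixels.

    Neighborhoods are read from the full image with reflect padding at the
    frame border, so context just outside a box still informs the
    convolution; only masked positions are written.
    """
    if mask.flags.shape != image.values.shape[:2]:
        raise ValidationError("mask shape does not match image")
    if not mask.flags.any() or kernel.k == 0:
        return ImageGrid(image.values.copy())
    v = image.values.astype(np.float64)
    blurred = np.empty_like(v)
    for c in range(v.shape[2]):
        blurred[:, :, c] = ndimage.correlate(v[:, :, c], kernel.weights, mode="reflect")
    out = image.values.copy()
    out[mask.flags] = _quantize(blurred)[mask.flags]
    return ImageGrid(out)


def focused_augment_image(
    item: LabeledImage,
    config: AugmentConfig,
    rng: np.random.Generator,
    suffix: str = "_faug",
) -> LabeledImage:
    """Noise-then-blur the target-class box union of one image.

    Boxes are copied verbatim (the geometry is untouched); the returned
    image id is the original id plus ``suffix``. An image without target
    boxes is emitted unchanged apart from its id.
    """
    mask = build_mask(item.boxes, config.target_classes, item.image.width, item.image.height)
    noisy = speckle_noise(item.image, mask, config.sigma_speckle, rng)
    kernel = make_gaussian_kernel(config.kernel_size, config.sigma_blur)
    smoothed = blur_region(noisy, mask, kernel)
    return LabeledImage(item.image_id + suffix, smoothed, item.boxes)


def augment_training_set(
    train: Sequence[LabeledImage], config: AugmentConfig
) -> list[LabeledImage]:
    """Merge the originals with their focused-augmented copies.

    With ``copies_per_image = 1`` the split doubles in size. Each copy's
    noise stream is derived from (seed, image id, copy index), so output
    pixels do not depend on the order of the input sequence.
    """
    if not train:
        raise ConfigError("training set must be non-empty")
    out = list(train)
    for item in train:
        for copy in range(config.copies_per_image):
            rng = rng_for(config.seed, item.image_id, copy)
            out.append(focused_augment_image(item, config, rng, suffix=f"_faug{copy}"))
    return out
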