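"""Detection-dataset primitives.

Normalized bounding boxes in the ``class cx cy w h`` text dialect, 8-bit
image rasters, train/val/test splitting, and lossless round-trip I/O for a
dataset laid out as ``<root>/<split>/images/*.png`` + ``<root>/<split>/
labels/*.txt`` with a YAML manifest.

Coordinates are fractions of image width/height; pixel space is 0-based
with half-open intervals, and normalized boxes are expanded outward
(floor/ceil) when rasterized so the continuous annotation is never
under-covered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from PIL import Image

from .errors import (
    DatasetError,
    DegenerateBoxError,
    ConfigError,
    LabelParseError,
    ValidationError,
)

#: slack accepted when a box extends past [0, 1] (annotation-tool slop);
#: such boxes are clamped on construction, larger violations are errors.
CLAMP_TOL = 1e-6
#: numerical tolerance on the containment invariant itself.
EDGE_TOL = 1e-9

SPLIT_NAMES = ("train", "val", "test")


@dataclass(frozen=True)
class NormBox:
    """A class-labeled box with center/extent as fractions of the frame."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not isinstance(self.class_id, (int, np.integer)) or self.class_id < 0:
            raise ValidationError(f"class_id must be a non-negative integer, got {self.class_id!r}")
        object.__setattr__(self, "class_id", int(self.class_id))
        for name in ("cx", "cy", "w", "h"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v!r}")
            object.__setattr__(self, name, float(v))
        if self.w <= 0 or self.h <= 0:
            raise ValidationError(f"box extents must be positive, got w={self.w}, h={self.h}")
        clamped = _clamp_extent(self.cx, self.w)
        if clamped is None:
            raise ValidationError(f"box exceeds [0,1] horizontally: cx={self.cx}, w={self.w}")
        object.__setattr__(self, "cx", clamped[0])
        object.__setattr__(self, "w", clamped[1])
        clamped = _clamp_extent(self.cy, self.h)
        if clamped is None:
            raise ValidationError(f"box exceeds [0,1] vertically: cy={self.cy}, h={self.h}")
        object.__setattr__(self, "cy", clamped[0])
        object.__setattr__(self, "h", clamped[1])

    @property
    def x1(self) -> float:
        return self.cx - self.w / 2

    @property
    def x2(self) -> float:
        return self.cx + self.w / 2

    @property
    def y1(self) -> float:
        return self.cy - self.h / 2

    @property
    def y2(self) -> float:
        return self.cy + self.h / 2

    @property
    def area(self) -> float:
        return self.w * self.h


def _clamp_extent(center: float, extent: float) -> tuple[float, float] | None:
    """Clamp a (center, extent) pair whose span leaks past [0,1] by <= CLAMP_TOL."""
    lo, hi = center - extent / 2, center + extent / 2
    if lo < -CLAMP_TOL or hi > 1 + CLAMP_TOL:
        return None
    if lo >= 0.0 and hi <= 1.0:
        return center, extent  # no clamping needed; keep exact values
    lo = max(lo, 0.0)
    hi = min(hi, 1.0)
    if hi <= lo:
        return None
    return (lo + hi) / 2, hi - lo


@dataclass(frozen=True)
class PixelBox:
    """A half-open pixel rectangle [x1, x2) x [y1, y2), 0-based."""

    x1: int
    y1: int
    x2: int
    y2: int

    def __post_init__(self) -> None:
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise DegenerateBoxError(f"empty pixel region {self!r}")
        if min(self.x1, self.y1) < 0:
            raise ValidationError(f"negative pixel coordinate in {self!r}")

    @property
    def width(self) -> int:
        return self.x2 - self.x1

    @property
    def height(self) -> int:
        return self.y2 - self.y1


@dataclass(frozen=True)
class ImageGrid:
    """An 8-bit raster of shape (H, W, C) with C in {1, 3}."""

    values: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.values)
        if a.ndim == 2:
            a = a[:, :, None]
        if a.ndim != 3 or a.shape[2] not in (1, 3):
            raise ValidationError(f"image must have shape (H, W, C) with C in {{1,3}}, got {a.shape}")
        if a.shape[0] < 8 or a.shape[1] < 8:
            raise ValidationError(f"image must be at least 8x8, got {a.shape[:2]}")
        if a.dtype != np.uint8:
            if np.any((a < 0) | (a > 255)):
                raise ValidationError("pixel values outside [0, 255]")
            a = a.astype(np.uint8)
        a = np.ascontiguousarray(a)
        a.setflags(write=False)
        object.__setattr__(self, "values", a)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def channels(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class LabeledImage:
    """An image together with its (possibly empty) box annotations."""

    image_id: str
    image: ImageGrid
    boxes: tuple[NormBox, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "boxes", tuple(self.boxes))

    def with_image(self, image: ImageGrid, image_id: str | None = None) -> "LabeledImage":
        return replace(self, image=image, image_id=image_id or self.image_id)


@dataclass
class DetDataset:
    """Class names plus per-split image sequences."""

    class_names: dict[int, str]
    splits: dict[str, list[LabeledImage]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for split in self.splits:
            if split not in SPLIT_NAMES:
                raise ValidationError(f"unknown split name {split!r}; expected one of {SPLIT_NAMES}")
        known = set(self.class_names)
        for split, items in self.splits.items():
            ids = [it.image_id for it in items]
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate image_id in split {split!r}")
            for it in items:
                for b in it.boxes:
                    if b.class_id not in known:
                        raise ValidationError(
                            f"box class {b.class_id} on image {it.image_id!r} not in class_names"
                        )


# ---------------------------------------------------------------------------
# label text dialect


def parse_label_file(text: str) -> list[NormBox]:
    """Parse ``class cx cy w h`` lines into boxes, preserving order.

    Raises :class:`LabelParseError` naming the 1-based line number for any
    malformed line (wrong token count, non-numeric, out of range).
    """
    boxes: list[NormBox] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        tokens = line.split()
        if len(tokens) != 5:
            raise LabelParseError(f"line {lineno}: expected 5 tokens, got {len(tokens)}")
        try:
            class_id = int(tokens[0])
            cx, cy, w, h = (float(t) for t in tokens[1:])
        except ValueError as exc:
            raise LabelParseError(f"line {lineno}: non-numeric token ({exc})") from exc
        try:
            boxes.append(NormBox(class_id, cx, cy, w, h))
        except ValidationError as exc:
            raise LabelParseError(f"line {lineno}: {exc}") from exc
    return boxes


def write_label_file(boxes: Sequence[NormBox]) -> str:
    """Render boxes as 6-decimal fixed-point lines, one box per line."""
    return "".join(
        f"{b.class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}\n" for b in boxes
    )


# ---------------------------------------------------------------------------
# pixel-space realization


def to_pixel(box: NormBox, W: int, H: int) -> PixelBox:
    """Rasterize a normalized box to the smallest covering pixel rectangle.

    floor/ceil expansion guarantees the continuous rectangle is a subset of
    the returned half-open region.
    """
    if W < 1 or H < 1:
        raise ConfigError(f"image dimensions must be >= 1, got {W}x{H}")
    # the epsilon snaps grid-aligned coordinates that float products push
    # a hair past an integer (e.g. 0.2 * 100 = 20.000000000000004)
    eps = 1e-9
    x1 = max(0, math.floor(box.x1 * W + eps))
    x2 = min(W, math.ceil(box.x2 * W - eps))
    y1 = max(0, math.floor(box.y1 * H + eps))
    y2 = min(H, math.ceil(box.y2 * H - eps))
    if x1 >= x2 or y1 >= y2:
        raise DegenerateBoxError(f"box {box} maps to an empty region on a {W}x{H} frame")
    return PixelBox(x1, y1, x2, y2)


# ---------------------------------------------------------------------------
# splitting


def split_dataset(
    items: Sequence[LabeledImage],
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> tuple[list[LabeledImage], list[LabeledImage], list[LabeledImage]]:
    """Random disjoint train/val/test partition with deterministic counts.

    Counts are round(n*f_train) and round(n*f_val); the remainder goes to
    test. Shuffling uses ``numpy.random.default_rng(seed)`` so the same seed
    always yields the same partition.
    """
    f = tuple(float(x) for x in fractions)
    if len(f) != 3 or any(x <= 0 for x in f):
        raise ConfigError(f"fractions must be three positive values, got {fractions!r}")
    if abs(sum(f) - 1.0) > 1e-9:
        raise ConfigError(f"fractions must sum to 1, got sum {sum(f)!r}")
    n = len(items)
    n_train = int(math.floor(n * f[0] + 0.5))
    n_val = int(math.floor(n * f[1] + 0.5))
    perm = np.random.default_rng(seed).permutation(n)
    train = [items[i] for i in perm[:n_train]]
    val = [items[i] for i in perm[n_train : n_train + n_val]]
    test = [items[i] for i in perm[n_train + n_val :]]
    return train, val, test


# ---------------------------------------------------------------------------
# disk I/O

MANIFEST_NAME = "manifest.yaml"
_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


def _labels_dir_for(images_dir: Path) -> Path:
    if images_dir.name == "images":
        return images_dir.parent / "labels"
    return images_dir.parent / (images_dir.name + "_labels")


def save_dataset(ds: DetDataset, root: str | Path) -> Path:
    """Write PNG images, label files, and a YAML manifest under ``root``."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"names": {int(k): v for k, v in ds.class_names.items()}}
    for split, items in ds.splits.items():
        images_dir = root / split / "images"
        labels_dir = root / split / "labels"
        images_dir.mkdir(parents=True, exist_ok=True)
        labels_dir.mkdir(parents=True, exist_ok=True)
        manifest[split] = f"{split}/images"
        for item in items:
            arr = item.image.values
            pil = Image.fromarray(arr[:, :, 0] if arr.shape[2] == 1 else arr)
            pil.save(images_dir / f"{item.image_id}.png")
            (labels_dir / f"{item.image_id}.txt").write_text(
                write_label_file(item.boxes), encoding="utf-8"
            )
    with open(root / MANIFEST_NAME, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return root / MANIFEST_NAME


def load_dataset(root: str | Path) -> DetDataset:
    """Load a dataset written by :func:`save_dataset` (or any compatible layout).

    An image with no label file gets an empty box list. Unreadable images and
    split directories named by the manifest but missing on disk raise
    :class:`DatasetError`.
    """
    root = Path(root)
    manifest_path = root if root.is_file() else root / MANIFEST_NAME
    root = manifest_path.parent
    if not manifest_path.exists():
        raise DatasetError(f"no manifest at {manifest_path}")
    manifest = yaml.safe_load(manifest_path.read_text(encoding="utf-8"))
    names = {int(k): str(v) for k, v in manifest.get("names", {}).items()}
    splits: dict[str, list[LabeledImage]] = {}
    for split in SPLIT_NAMES:
        if split not in manifest:
            continue
        images_dir = root / manifest[split]
        if not images_dir.is_dir():
            raise DatasetError(f"manifest names split {split!r} but {images_dir} is missing")
        labels_dir = _labels_dir_for(images_dir)
        items: list[LabeledImage] = []
        for path in sorted(images_dir.iterdir()):
            if path.suffix.lower() not in _IMAGE_SUFFIXES:
                continue
            try:
                with Image.open(path) as pil:
                    pil = pil.convert("RGB") if pil.mode not in ("L", "RGB") else pil
                    arr = np.asarray(pil)
            except OSError as exc:
                raise DatasetError(f"unreadable image {path}: {exc}") from exc
            label_path = labels_dir / (path.stem + ".txt")
            boxes: list[NormBox] = []
            if label_path.exists():
                try:
                    boxes = parse_label_file(label_path.read_text(encoding="utf-8"))
                except LabelParseError as exc:
                    raise LabelParseError(f"{label_path}: {exc}") from exc
            for b in boxes:
                if b.class_id not in names:
                    raise ValidationError(
                        f"{label_path}: class {b.class_id} not declared in manifest names"
                    )
            items.append(LabeledImage(path.stem, ImageGrid(arr), tuple(boxes)))
        splits[split] = items
    return DetDataset(class_names=names, splits=splits)
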