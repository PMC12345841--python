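"""Conventional whole-image augmentation: rotation, photometry, blur.

Shows the global baseline strategy on a phantom training split and how
rotation transforms box geometry (axis-aligned envelope of the rotated
corners, with low-visibility boxes dropped).
"""

import numpy as np

from focalaug import (
    GlobalAugmentConfig,
    NormBox,
    PhantomConfig,
    conventional_augment_set,
    generate_phantom,
    rotate_image_and_boxes,
)

phantom = generate_phantom(PhantomConfig(image_size=128, seed=3), np.random.default_rng(3), "demo")

# one explicit rotation: a box near the upper-left quarter, turned 30 degrees
box = NormBox(1, 0.30, 0.30, 0.10, 0.06)
_, rotated = rotate_image_and_boxes(phantom.image, [box], 30.0)
b = rotated[0]
print(f"box before: center ({box.cx:.3f}, {box.cy:.3f}), size ({box.w:.3f} x {box.h:.3f})")
print(f"box after 30 deg: center ({b.cx:.3f}, {b.cy:.3f}), size ({b.w:.3f} x {b.h:.3f})")
# The envelope grows (w and h increase): it is the tightest axis-aligned
# box containing the rotated rectangle.

merged = conventional_augment_set([phantom], GlobalAugmentConfig(seed=3))
print(f"training set: 1 original -> {len(merged)} items (dataset doubled)")
variant = merged[1]
print(f"variant id: {variant.image_id}; boxes kept: {len(variant.boxes)}/{len(phantom.boxes)}")
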