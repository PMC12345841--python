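"""Deterministic per-item random streams.

Augmentation and simulation draw from a stream keyed on
(run seed, item id, copy index), so results do not depend on the order in
which items are processed and stay reproducible across platforms.
"""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(seed: int, *keys: object) -> int:
    """Mix a run seed with string/int keys into a 31-bit child seed."""
    digest = hashlib.sha256(
        ("\x1f".join(str(k) for k in (seed, *keys))).encode("utf-8")
    ).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def rng_for(seed: int, *keys: object) -> np.random.Generator:
    """A fresh Generator for the given (seed, keys) combination."""
    return np.random.default_rng(derive_seed(seed, *keys))
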