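"""Independent reference implementations used only by the tests.

Each oracle is deliberately naive (explicit loops, direct definitions) so
it shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def reflect_index(i: int, n: int) -> int:
    """Edge-inclusive symmetric reflection: -1 -> 0, n -> n-1, n+1 -> n-2."""
    while i < 0 or i >= n:
        if i < 0:
            i = -i - 1
        if i >= n:
            i = 2 * n - i - 1
    return i


def naive_blur(plane: np.ndarray, weights: np.ndarray, k: int) -> np.ndarray:
    """Quadruple-loop windowed sum with reflect padding."""
    H, W = plane.shape
    out = np.empty((H, W), dtype=np.float64)
    for y in range(H):
        for x in range(W):
            acc = 0.0
            for di in range(-k, k + 1):
                for dj in range(-k, k + 1):
                    acc += plane[reflect_index(y + di, H), reflect_index(x + dj, W)] \
                        * weights[di + k, dj + k]
            out[y, x] = acc
    return out


def naive_quantize(a: np.ndarray) -> np.ndarray:
    return np.floor(np.clip(a, 0, 255) + 0.5).astype(np.uint8)


def brute_force_ap(flags, confidences, n_gt: int) -> float:
    """Explicit envelope construction and 101-point grid sum."""
    order = sorted(range(len(flags)), key=lambda i: (-confidences[i], i))
    tp = 0
    points = []  # (recall, precision)
    for rank, i in enumerate(order, start=1):
        tp += bool(flags[i])
        points.append((tp / n_gt, tp / rank))
    total = 0.0
    for g in range(101):
        r = g / 100.0
        candidates = [p for rec, p in points if rec >= r]
        total += max(candidates) if candidates else 0.0
    return total / 101.0


def rotated_point_envelope(box, angle_deg: float, W: int, H: int,
                           density: int = 60) -> tuple[float, float, float, float]:
    """Envelope of a dense grid of points inside the box after exact rotation.

    By convexity this converges to the rotated-corner envelope as density
    grows; it is an independent check on the corner-based implementation.
    """
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    xs = np.linspace(box.x1 * W, box.x2 * W, density)
    ys = np.linspace(box.y1 * H, box.y2 * H, density)
    gx, gy = np.meshgrid(xs, ys)
    px, py = gx.ravel() - W / 2.0, gy.ravel() - H / 2.0
    rx = c * px - s * py + W / 2.0
    ry = s * px + c * py + H / 2.0
    return float(rx.min()), float(ry.min()), float(rx.max()), float(ry.max())
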