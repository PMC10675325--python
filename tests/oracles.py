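"""Independent brute-force oracles the tests check the library against.

These deliberately avoid the library's own code paths (and the scipy /
scikit-image routines behind them): flood fill by an explicit stack,
circle rasterization by a double loop, least squares by the normal
equations, Pearson r by direct summation.
"""

from __future__ import annotations

import numpy as np


def flood_fill_components(values: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected components by stack-based flood fill.

    Labels are assigned in raster-scan order of each component's first
    pixel.  Returns (label_map, n_components).
    """
    H, W = values.shape
    labels = np.zeros((H, W), dtype=np.int32)
    current = 0
    for r0 in range(H):
        for c0 in range(W):
            if values[r0, c0] and labels[r0, c0] == 0:
                current += 1
                labels[r0, c0] = current
                stack = [(r0, c0)]
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < H and 0 <= cc < W
                                    and values[rr, cc]
                                    and labels[rr, cc] == 0):
                                labels[rr, cc] = current
                                stack.append((rr, cc))
    return labels, current


def circle_pixel_count(shape: tuple[int, int], cy: float, cx: float,
                       radius: float) -> int:
    """Pixels whose center (row, col) lies within the circle, by brute force."""
    n = 0
    r2 = radius * radius
    for r in range(shape[0]):
        for c in range(shape[1]):
            if (r - cy) ** 2 + (c - cx) ** 2 <= r2:
                n += 1
    return n


def remove_small_regions(values: np.ndarray, min_px: int) -> np.ndarray:
    """Flood-fill-then-filter reference for mask cleaning."""
    labels, n = flood_fill_components(values)
    out = values.copy()
    for k in range(1, n + 1):
        sel = labels == k
        if sel.sum() < min_px:
            out[sel] = False
    return out


def ols_line(x, y) -> tuple[float, float]:
    """Least-squares line by the closed-form normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def pearson_direct(x, y) -> float:
    """Pearson r by direct summation of the defining formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - x.mean()
    dy = y - y.mean()
    return float((dx * dy).sum()
                 / np.sqrt((dx * dx).sum() * (dy * dy).sum()))
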