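"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written for clarity, not speed: nested loops, explicit
padding, direct definitions. These functions never call the package code
they check.
"""

from __future__ import annotations

import numpy as np


def capsule_mask(segments, shape, pitch):
    """Per-pixel point-in-capsule test: pixel centers at (i+0.5, j+0.5)*pitch.

    ``segments`` is an iterable of ((ax, ay), (bx, by), radius) in mm.
    """
    rows, cols = shape
    out = np.zeros(shape, dtype=bool)
    for i in range(rows):
        y = (i + 0.5) * pitch
        for j in range(cols):
            x = (j + 0.5) * pitch
            for (ax, ay), (bx, by), radius in segments:
                dx, dy = bx - ax, by - ay
                L2 = dx * dx + dy * dy
                t = ((x - ax) * dx + (y - ay) * dy) / L2
                t = min(max(t, 0.0), 1.0)
                px, py = ax + t * dx, ay + t * dy
                if (x - px) ** 2 + (y - py) ** 2 <= radius**2:
                    out[i, j] = True
                    break
    return out


def _pad_sym(img, r):
    return np.pad(img, r, mode="symmetric")


def sliding_median(img, radius):
    """Median over a (2r+1)^2 window with symmetric border padding."""
    r = radius
    padded = _pad_sym(img, r)
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = np.median(padded[i : i + 2 * r + 1, j : j + 2 * r + 1])
    return out


def gaussian_conv(img, sigma, truncate=4.0):
    """Direct separable convolution with the truncated sampled Gaussian."""
    r = int(truncate * sigma + 0.5)
    x = np.arange(-r, r + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    padded = _pad_sym(img, r)
    tmp = np.empty((img.shape[0], padded.shape[1]))
    for j in range(padded.shape[1]):
        for i in range(img.shape[0]):
            tmp[i, j] = padded[i : i + 2 * r + 1, j].dot(kernel)
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = tmp[i, j : j + 2 * r + 1].dot(kernel)
    return out


def disk_footprint(radius):
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return x * x + y * y <= radius * radius


def grey_opening(img, radius):
    """Erosion then dilation with a disk, symmetric padding, direct min/max."""
    fp = disk_footprint(radius)
    offs = np.argwhere(fp) - radius

    def _erode(a):
        padded = _pad_sym(a, radius)
        out = np.empty_like(a, dtype=float)
        for i in range(a.shape[0]):
            for j in range(a.shape[1]):
                out[i, j] = min(
                    padded[i + radius + di, j + radius + dj] for di, dj in offs
                )
        return out

    def _dilate(a):
        padded = _pad_sym(a, radius)
        out = np.empty_like(a, dtype=float)
        for i in range(a.shape[0]):
            for j in range(a.shape[1]):
                out[i, j] = max(
                    padded[i + radius + di, j + radius + dj] for di, dj in offs
                )
        return out

    return _dilate(_erode(img))


def label_areas_8conn(mask):
    """Connected-component areas by explicit flood fill (8-connectivity)."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    areas = []
    rows, cols = mask.shape
    for i in range(rows):
        for j in range(cols):
            if mask[i, j] and not seen[i, j]:
                stack = [(i, j)]
                seen[i, j] = True
                area = 0
                while stack:
                    a, b = stack.pop()
                    area += 1
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            na, nb = a + da, b + db
                            if (
                                0 <= na < rows
                                and 0 <= nb < cols
                                and mask[na, nb]
                                and not seen[na, nb]
                            ):
                                seen[na, nb] = True
                                stack.append((na, nb))
                areas.append(area)
    return areas


def count_true(mask):
    """Nested-loop pixel count."""
    total = 0
    for row in np.asarray(mask, bool):
        for v in row:
            if v:
                total += 1
    return total
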