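"""Independent brute-force oracles used to pin down the numeric operations.

These deliberately avoid the library code paths they check: dense double
loops for convolution, per-tap inverse mapping for rotation, an explicit
CDF table for equalization.
"""

from __future__ import annotations

import numpy as np


def conv_oracle(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Dense double-loop TRUE convolution with symmetric border padding."""
    image = np.asarray(image, dtype=np.float64)
    kernel = np.asarray(kernel, dtype=np.float64)
    ky, kx = kernel.shape
    py, px = ky // 2, kx // 2
    padded = np.pad(image, ((py, py), (px, px)), mode="symmetric")
    out = np.zeros_like(image)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            acc = 0.0
            for a in range(ky):
                for b in range(kx):
                    acc += kernel[a, b] * padded[i + ky - 1 - a, j + kx - 1 - b]
            out[i, j] = acc
    return out


def rotate_oracle(taps: np.ndarray, angle_deg: float) -> np.ndarray:
    """Per-tap inverse-mapping bilinear rotation about the kernel center."""
    taps = np.asarray(taps, dtype=np.float64)
    side = taps.shape[0]
    c = (side - 1) / 2.0
    theta = np.deg2rad(angle_deg)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    out = np.zeros_like(taps)
    for i in range(side):
        for j in range(side):
            dy, dx = i - c, j - c
            sy = -sin_t * dx + cos_t * dy + c
            sx = cos_t * dx + sin_t * dy + c
            y0, x0 = int(np.floor(sy)), int(np.floor(sx))
            fy, fx = sy - y0, sx - x0
            val = 0.0
            for (yy, wy) in ((y0, 1 - fy), (y0 + 1, fy)):
                for (xx, wx) in ((x0, 1 - fx), (x0 + 1, fx)):
                    if 0 <= yy < side and 0 <= xx < side:
                        val += wy * wx * taps[yy, xx]
            out[i, j] = val
    return out


def equalize_oracle(values: np.ndarray) -> np.ndarray:
    """Textbook 256-bin CDF equalization table applied value by value."""
    q = np.clip(np.round(values), 0, 255).astype(int)
    n = q.size
    counts = {}
    for v in q.ravel():
        counts[v] = counts.get(v, 0) + 1
    levels = sorted(counts)
    cdf = {}
    running = 0
    for lv in levels:
        running += counts[lv]
        cdf[lv] = running
    cdf_min = counts[levels[0]]
    out = np.zeros_like(values, dtype=float)
    for idx, v in np.ndenumerate(q):
        if n == cdf_min:
            out[idx] = 0.0
        else:
            out[idx] = round(255.0 * (cdf[v] - cdf_min) / (n - cdf_min))
    return out
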