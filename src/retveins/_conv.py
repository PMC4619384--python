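"""Shared numeric primitives: reflected-border convolution and bilinear kernel rotation.

Both are used by several filter modules and are pinned down here so every
stage shares one border policy (half-sample symmetric reflection) and one
rotation convention (inverse-mapping bilinear interpolation about the
kernel center, out-of-support samples zero).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal

# Direct convolution up to this many multiply-accumulates; FFT above it.
_DIRECT_MACS = 1 << 26


def convolve_reflect(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """True 2-D convolution with half-sample symmetric border reflection.

    Equivalent to ``scipy.ndimage.convolve(image, kernel, mode='reflect')``;
    large kernels are routed through an FFT on a symmetric-padded copy for
    speed.  The image must be at least as large as the kernel in both axes.
    """
    image = np.asarray(image, dtype=np.float64)
    kernel = np.asarray(kernel, dtype=np.float64)
    if kernel.shape[0] > image.shape[0] or kernel.shape[1] > image.shape[1]:
        raise ValueError(
            f"kernel {kernel.shape} larger than image {image.shape}"
        )
    if kernel.size * image.size <= _DIRECT_MACS:
        return ndimage.convolve(image, kernel, mode="reflect")
    py, px = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(image, ((py, py), (px, px)), mode="symmetric")
    return signal.fftconvolve(padded, kernel, mode="valid")


def rotate_taps(taps: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a square kernel about its center by bilinear interpolation.

    Inverse mapping: each output tap samples the input at the back-rotated
    location; samples falling outside the support are zero.  Angles are in
    degrees; grid-aligned rotations (multiples of 90°) reduce to exact
    array rotations up to floating-point round-off.
    """
    taps = np.asarray(taps, dtype=np.float64)
    side = taps.shape[0]
    if taps.shape != (side, side):
        raise ValueError("kernel must be square")
    c = (side - 1) / 2.0
    theta = np.deg2rad(angle_deg)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    rows, cols = np.mgrid[0:side, 0:side]
    dy, dx = rows - c, cols - c
    # back-rotate the output offset to find the source sample
    sx = cos_t * dx + sin_t * dy
    sy = -sin_t * dx + cos_t * dy
    coords = np.stack([c + sy, c + sx])
    # grid-constant: bilinear weights fade to zero across the support edge
    return ndimage.map_coordinates(taps, coords, order=1, mode="grid-constant", cval=0.0)
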