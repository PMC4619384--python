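"""Raster I/O and the shared image/mask types.

Every stage of the segmentation pipeline passes 2-D rasters around in two
forms: :class:`GrayImage`, a scalar raster with a declared intensity range
and an optional field-of-view (FOV) mask, and ``BinaryMask``, a plain 2-D
boolean :class:`numpy.ndarray`.  Coordinates are 0-based ``(row, col)`` with
row 0 at the top; all modules share this convention.

Fundus photographs carry a circular FOV: only pixels inside it show retina,
and histogram-based operations here (equalization, proportion thresholding)
are restricted to the FOV when one is attached.  When no FOV is given the
whole frame counts as FOV.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "BinaryMask",
    "GrayImage",
    "read_image",
    "read_mask",
    "write_mask",
    "write_image",
    "normalize_to_byte",
    "equalize_histogram",
    "discover_drive",
    "discover_stare",
]

# A BinaryMask is simply a 2-D boolean ndarray; the alias documents intent.
BinaryMask = np.ndarray

_RANGES = {"byte": (0.0, 255.0), "unit": (0.0, 1.0), "signed": None}


@dataclass
class GrayImage:
    """A 2-D scalar raster with intensity-range metadata and optional FOV.

    Parameters
    ----------
    pixels
        2-D float array, shape ``(M, N)`` = (height, width).
    range
        ``'byte'`` for values in [0, 255], ``'unit'`` for [0, 1] and
        ``'signed'`` for unconstrained intermediates (e.g. the bias-removed
        image before renormalization).
    fov
        Optional boolean mask of identical shape; ``None`` means the whole
        frame is inside the field of view.
    """

    pixels: np.ndarray
    range: str = "byte"
    fov: BinaryMask | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if self.range not in _RANGES:
            raise ValueError(f"unknown range {self.range!r}")
        bounds = _RANGES[self.range]
        if bounds is not None:
            lo, hi = bounds
            pmin, pmax = float(self.pixels.min()), float(self.pixels.max())
            if pmin < lo - 1e-9 or pmax > hi + 1e-9:
                raise ValueError(
                    f"pixel values [{pmin}, {pmax}] outside declared "
                    f"{self.range} range [{lo}, {hi}]"
                )
        if self.fov is not None:
            self.fov = np.asarray(self.fov, dtype=bool)
            if self.fov.shape != self.pixels.shape:
                raise ValueError("fov shape differs from pixels shape")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def fov_or_full(self) -> BinaryMask:
        """The attached FOV, or an all-true mask when none is attached."""
        if self.fov is None:
            return np.ones(self.pixels.shape, dtype=bool)
        return self.fov


def _load_raster(path: str | Path) -> np.ndarray:
    try:
        arr = iio.imread(path)
    except Exception as exc:  # unreadable / missing file
        raise IOError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 4:  # animated formats (GIF): take the first frame
        arr = arr[0]
    return arr


def read_image(path: str | Path, channel: str = "green") -> GrayImage:
    """Read a fundus image and extract one scalar plane.

    ``channel='green'`` selects the green plane of a color image — the plane
    where vessels have the highest contrast against the background (the blue
    plane tends to be empty and the red one saturated).  ``'gray'`` passes a
    single-plane image through unchanged and converts color input by Rec.601
    luminance; ``'as-is'`` accepts single-plane input only.
    """
    arr = _load_raster(path)
    if channel == "green":
        if arr.ndim != 3 or arr.shape[-1] < 3:
            raise ValueError(f"green channel requested but {path} has no 3 color planes")
        plane = arr[..., 1]
    elif channel == "gray":
        if arr.ndim == 2:
            plane = arr
        elif arr.ndim == 3 and arr.shape[-1] >= 3:
            rgb = arr[..., :3].astype(np.float64)
            plane = rgb @ np.array([0.299, 0.587, 0.114])
        else:
            raise ValueError(f"cannot interpret {path} (shape {arr.shape}) as gray")
    elif channel == "as-is":
        if arr.ndim != 2:
            raise ValueError(f"channel='as-is' requires a single-plane image, got {arr.shape}")
        plane = arr
    else:
        raise ValueError(f"unknown channel {channel!r}")
    return GrayImage(np.clip(plane.astype(np.float64), 0.0, 255.0), range="byte")


def read_mask(path: str | Path, threshold: int = 127) -> BinaryMask:
    """Read a raster as a binary mask: pixels strictly above ``threshold`` are true."""
    arr = _load_raster(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return np.asarray(arr) > threshold


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    """Write a binary mask as an 8-bit raster with values {0, 255}."""
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def write_image(path: str | Path, img: GrayImage) -> None:
    """Write a byte-range image as 8-bit (values rounded and clipped)."""
    iio.imwrite(path, np.clip(np.round(img.pixels), 0, 255).astype(np.uint8))


def normalize_to_byte(img: GrayImage) -> GrayImage:
    """Affinely map ``[min, max]`` of the image onto ``[0, 255]``.

    A constant image has no contrast to stretch; by convention it maps to
    all zeros (a warning is emitted).  The operation is idempotent on its
    own output.
    """
    pix = img.pixels
    lo, hi = float(pix.min()), float(pix.max())
    if hi - lo == 0.0:
        warnings.warn("normalize_to_byte: constant image, returning all zeros")
        out = np.zeros_like(pix)
    else:
        out = (pix - lo) * (255.0 / (hi - lo))
    return GrayImage(out, range="byte", fov=img.fov)


def equalize_histogram(img: GrayImage) -> GrayImage:
    """256-bin cumulative-histogram equalization restricted to the FOV.

    Pixels are quantized to integer bins 0..255, the CDF is accumulated over
    FOV pixels only, and each FOV pixel is remapped to
    ``round(255 * (cdf(bin) - cdf_min) / (n_fov - cdf_min))`` where
    ``cdf_min`` is the CDF at the lowest occupied bin, so the darkest
    occupied bin maps to 0 (and a constant image maps to all zeros).
    Pixels outside the FOV are left unchanged (the black border of a fundus
    photograph would otherwise dominate the histogram).  The remap is
    monotone, so pixel rank order is preserved (ties allowed).
    """
    if img.range != "byte":
        raise ValueError("equalize_histogram expects a byte-range image")
    fov = img.fov_or_full()
    q = np.clip(np.round(img.pixels), 0, 255).astype(np.int64)
    hist = np.bincount(q[fov], minlength=256)
    n = hist.sum()
    if n == 0:
        raise ValueError("empty FOV")
    cdf = np.cumsum(hist)
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    if n == cdf_min:  # single occupied bin: no contrast to spread
        lut = np.zeros(256)
    else:
        lut = np.round(255.0 * (cdf - cdf_min) / (n - cdf_min))
    out = img.pixels.copy()
    out[fov] = lut[q[fov]]
    return GrayImage(out, range="byte", fov=img.fov)


# ---------------------------------------------------------------------------
# Benchmark directory layouts (discovery only; data is user-supplied)

def discover_drive(root: str | Path) -> list[dict]:
    """Discover the DRIVE layout: ``NN_test.tif`` / ``NN_manual1.gif`` / ``NN_test_mask.gif``.

    Returns one record per image with keys ``image``, ``gold``, ``fov``
    (``gold``/``fov`` may be ``None`` when missing).  Searches recursively,
    so the standard ``images/``, ``1st_manual/``, ``mask/`` subfolders work.
    """
    root = Path(root)
    records = []
    for img in sorted(root.rglob("*_test.tif")) + sorted(root.rglob("*_training.tif")):
        m = re.match(r"(\d+)_", img.name)
        if not m:
            continue
        idx = m.group(1)
        golds = list(root.rglob(f"{idx}_manual1.gif"))
        fovs = list(root.rglob(f"{idx}_*mask.gif"))
        records.append(
            {
                "name": img.stem,
                "image": img,
                "gold": golds[0] if golds else None,
                "fov": fovs[0] if fovs else None,
            }
        )
    return records


def discover_stare(root: str | Path) -> list[dict]:
    """Discover the STARE layout: ``imNNNN.ppm`` images with ``imNNNN.ah.ppm`` gold."""
    root = Path(root)
    records = []
    for img in sorted(root.rglob("im*.ppm")):
        if ".ah" in img.name or ".vk" in img.name:
            continue
        stem = img.name.split(".")[0]
        golds = list(root.rglob(f"{stem}.ah.ppm"))
        records.append(
            {
                "name": stem,
                "image": img,
                "gold": golds[0] if golds else None,
                "fov": None,
            }
        )
    return records
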