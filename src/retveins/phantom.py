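"""Seeded synthetic fundus phantoms: vessel trees + gold mask + FOV.

A phantom emulates exactly the features the segmentation pipeline feeds
on: dark curvilinear vessel trees of varying width on a bright background,
a smooth low-frequency illumination bias, pixel-wise Gaussian noise, and a
circular field of view with a dark surround.  It deliberately does NOT
model optic disk or fovea anatomy, vessel texture, or photoreceptor
granularity.

Vessel trees are grown as random walks from seed points on the FOV rim:
headings drift by a curvature-bounded Gaussian increment per unit step,
branches split off probabilistically with reduced width, and widths taper
toward the minimum along the walk.  Each centerline point is rasterized as
a Gaussian cross-section whose FWHM equals the local width (stamps combine
by maximum, truncated at 3σ); the gold mask is the half-maximum set of the
rasterized depth, so a width-w straight vessel yields exactly a w-pixel
band.  Tree growth stops once the achieved vessel fraction of the FOV
reaches the target.

One integer seed governs every stochastic draw, with fixed substreams per
purpose (tree i, bias, noise, lesions), so adding a tree never reshuffles
earlier ones and the same spec + seed is bit-identical across runs.
Optional disk-shaped "lesion" distractors — dark compact blobs kept clear
of the vessels — exercise the speckle-removal rule downstream; they are
reported in a separate ``distractors`` layer, never in the gold mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import BinaryMask, GrayImage

__all__ = ["PhantomSpec", "Phantom", "generate", "fixture_suite", "stamp_centerline"]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.3548


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters; defaults give a DRIVE-like difficulty level.

    Intensities are gray levels on the byte scale: ``background`` is the
    retina level inside the FOV, ``vessel_depth`` the centerline intensity
    drop, ``bias_amplitude`` the max-abs excursion of the smooth bias field
    (correlation length ``bias_scale`` px), ``noise_sigma`` the std of the
    additive pixel noise.  ``target_vessel_frac`` is the gold fraction of
    the FOV at which tree growth stops (real fundus FOVs run ~0.09–0.13).
    """

    height: int = 256
    width: int = 256
    n_trees: int = 5
    branch_prob: float = 0.04
    width_range: tuple[float, float] = (1.0, 7.0)
    vessel_depth: float = 80.0
    background: float = 200.0
    bias_amplitude: float = 25.0
    bias_scale: float = 64.0
    noise_sigma: float = 6.0
    fov_radius_frac: float = 0.94
    target_vessel_frac: float = 0.09
    curvature_std: float = 0.08
    n_lesions: int = 0
    lesion_radius_range: tuple[float, float] = (4.0, 8.0)
    lesion_depth: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.width_range
        if not (1.0 <= lo <= hi <= 15.0):
            raise ValueError("width_range must lie within [1, 15]")
        if not 0.0 <= self.target_vessel_frac <= 0.2:
            raise ValueError("target_vessel_frac must lie in [0, 0.2]")
        if not 0.0 < self.fov_radius_frac <= 1.0:
            raise ValueError("fov_radius_frac must lie in (0, 1]")


@dataclass(frozen=True)
class Phantom:
    image: GrayImage
    gold: BinaryMask
    fov: BinaryMask
    achieved_vessel_frac: float
    distractors: BinaryMask
    spec: PhantomSpec


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def stamp_centerline(
    depth_map: np.ndarray, points: np.ndarray, widths: np.ndarray, depth: float
) -> None:
    """Rasterize centerline points as max-combined truncated Gaussian stamps.

    Each point (row, col) contributes ``depth·exp(−r²/(2σ²))`` with
    ``σ = width/2.3548`` (FWHM = width), truncated at 3σ.  In-place.
    """
    H, W = depth_map.shape
    for (py, px), w in zip(points, widths):
        sigma = max(float(w), 1e-6) / _FWHM
        rad = int(np.ceil(3.0 * sigma))
        iy, ix = int(round(py)), int(round(px))
        y0, y1 = max(iy - rad, 0), min(iy + rad + 1, H)
        x0, x1 = max(ix - rad, 0), min(ix + rad + 1, W)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
        r2 = (yy - py) ** 2 + (xx - px) ** 2
        stamp = depth * np.exp(-r2 / (2.0 * sigma**2))
        stamp[r2 > (3.0 * sigma) ** 2] = 0.0
        np.maximum(depth_map[y0:y1, x0:x1], stamp, out=depth_map[y0:y1, x0:x1])


def _grow_tree(
    rng: np.random.Generator, spec: PhantomSpec, radius: float, center: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """One vessel tree as centerline points + widths (random rim-seeded walk)."""
    cy, cx = center
    w_lo, w_hi = spec.width_range
    phi = rng.uniform(0.0, 2.0 * np.pi)
    y = cy + 0.92 * radius * np.sin(phi)
    x = cx + 0.92 * radius * np.cos(phi)
    heading = phi + np.pi + rng.uniform(-0.6, 0.6)
    w0 = w_lo + (w_hi - w_lo) * rng.uniform(0.4, 1.0)
    max_steps = int(2.5 * radius)
    taper = (w0 - w_lo) / max(max_steps, 1)
    points: list[tuple[float, float]] = []
    widths: list[float] = []
    stack = [(y, x, heading, w0, 0)]
    budget = int(8 * radius)  # total centerline length cap per tree
    while stack and len(points) < budget:
        y, x, h, w, steps = stack.pop()
        while steps < max_steps and len(points) < budget:
            if (y - cy) ** 2 + (x - cx) ** 2 > (0.98 * radius) ** 2 and steps > 2:
                break
            points.append((y, x))
            widths.append(w)
            y += np.sin(h)
            x += np.cos(h)
            h += rng.normal(0.0, spec.curvature_std)
            w = max(w - taper, w_lo)
            steps += 1
            if rng.random() < spec.branch_prob and steps > 8 and w > 1.3 * w_lo:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                stack.append((y, x, h + sign * rng.uniform(0.35, 0.9), 0.75 * w, steps))
                h -= 0.2 * sign
    return np.array(points, dtype=np.float64).reshape(-1, 2), np.array(widths)


def _place_lesions(
    rng: np.random.Generator, spec: PhantomSpec, gold: BinaryMask, radius: float,
    center: tuple[float, float],
) -> np.ndarray:
    """Depth map of disk distractors kept clear of the vessel mask."""
    H, W = gold.shape
    cy, cx = center
    depth_l = spec.lesion_depth if spec.lesion_depth is not None else 0.9 * spec.vessel_depth
    lesions = np.zeros((H, W))
    # keep-out zone: vessels dilated so elongation cannot bridge disk to vessel
    keep_out = ndimage.binary_dilation(gold, iterations=6)
    placed = 0
    for _ in range(60 * max(spec.n_lesions, 1)):
        if placed >= spec.n_lesions:
            break
        r_les = rng.uniform(*spec.lesion_radius_range)
        ang = rng.uniform(0.0, 2.0 * np.pi)
        rr = radius * 0.75 * np.sqrt(rng.uniform())
        ly, lx = cy + rr * np.sin(ang), cx + rr * np.cos(ang)
        margin = int(np.ceil(r_les)) + 3
        y0, y1 = int(ly) - margin, int(ly) + margin + 1
        x0, x1 = int(lx) - margin, int(lx) + margin + 1
        if y0 < 0 or x0 < 0 or y1 > H or x1 > W:
            continue
        if keep_out[y0:y1, x0:x1].any() or lesions[y0:y1, x0:x1].any():
            continue
        sigma_l = r_les / np.sqrt(2.0 * np.log(2.0))  # half-max at r_les
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
        r2 = (yy - ly) ** 2 + (xx - lx) ** 2
        stamp = depth_l * np.exp(-r2 / (2.0 * sigma_l**2))
        stamp[r2 > (3.0 * sigma_l) ** 2] = 0.0
        np.maximum(lesions[y0:y1, x0:x1], stamp, out=lesions[y0:y1, x0:x1])
        placed += 1
    if placed < spec.n_lesions:
        warnings.warn(f"placed only {placed}/{spec.n_lesions} lesions")
    return lesions


def generate(spec: PhantomSpec) -> Phantom:
    """Generate one phantom; deterministic in (spec, spec.seed)."""
    H, W = spec.height, spec.width
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    radius = spec.fov_radius_frac * min(H, W) / 2.0
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    fov = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    n_fov = int(fov.sum())

    depth_map = np.zeros((H, W))
    half = spec.vessel_depth / 2.0
    frac = 0.0
    grown = 0
    max_trees = max(4 * spec.n_trees, spec.n_trees)
    # stamp in short chunks so growth can stop mid-tree once the target
    # vessel fraction is reached (keeps the achieved fraction tight)
    chunk = 40
    while frac < spec.target_vessel_frac and grown < max_trees:
        points, widths = _grow_tree(_rng(spec.seed, 100 + grown), spec, radius, (cy, cx))
        for start in range(0, len(points), chunk):
            stamp_centerline(
                depth_map, points[start : start + chunk], widths[start : start + chunk],
                spec.vessel_depth,
            )
            frac = float((((depth_map >= half) & fov).sum()) / n_fov)
            if frac >= spec.target_vessel_frac:
                break
        grown += 1
    if frac < spec.target_vessel_frac and spec.target_vessel_frac > 0:
        warnings.warn(
            f"vessel fraction {frac:.4f} below target "
            f"{spec.target_vessel_frac:.4f} after {grown} trees; best effort"
        )
    gold = (depth_map >= half) & fov

    lesion_map = np.zeros((H, W))
    if spec.n_lesions > 0:
        lesion_map = _place_lesions(_rng(spec.seed, 7), spec, gold, radius, (cy, cx))
    depth_l = spec.lesion_depth if spec.lesion_depth is not None else 0.9 * spec.vessel_depth
    distractors = (lesion_map >= depth_l / 2.0) & fov

    if spec.bias_amplitude > 0:
        rough = _rng(spec.seed, 1).standard_normal((H, W))
        smooth = ndimage.gaussian_filter(rough, spec.bias_scale)
        peak = np.abs(smooth).max()
        bias = spec.bias_amplitude * smooth / peak if peak > 0 else np.zeros((H, W))
    else:
        bias = np.zeros((H, W))
    noise = (
        spec.noise_sigma * _rng(spec.seed, 3).standard_normal((H, W))
        if spec.noise_sigma > 0
        else np.zeros((H, W))
    )

    pixels = spec.background + bias - np.maximum(depth_map, lesion_map) + noise
    pixels = np.clip(np.round(pixels), 0.0, 255.0)
    pixels[~fov] = 0.0
    image = GrayImage(pixels, range="byte", fov=fov)
    return Phantom(image, gold, fov, float(gold.sum() / n_fov), distractors, spec)


def fixture_suite(seed: int) -> list[Phantom]:
    """The fixed five-phantom battery used by the end-to-end tests.

    (a) clean high-contrast, (b) heavy bias field, (c) high noise,
    (d) capillary-rich (widths 1–2.5 px), (e) clean with disk-shaped
    lesion distractors exercising the speckle rule.
    """
    specs = [
        PhantomSpec(vessel_depth=90.0, noise_sigma=2.0, bias_amplitude=5.0, seed=seed),
        PhantomSpec(vessel_depth=80.0, noise_sigma=4.0, bias_amplitude=60.0, seed=seed),
        PhantomSpec(vessel_depth=70.0, noise_sigma=15.0, bias_amplitude=20.0, seed=seed),
        PhantomSpec(
            vessel_depth=70.0,
            noise_sigma=4.0,
            bias_amplitude=15.0,
            width_range=(1.0, 2.5),
            target_vessel_frac=0.05,
            n_trees=8,
            seed=seed,
        ),
        PhantomSpec(
            vessel_depth=90.0,
            noise_sigma=2.0,
            bias_amplitude=5.0,
            n_lesions=6,
            lesion_radius_range=(4.0, 8.0),
            seed=seed,
        ),
    ]
    return [generate(s) for s in specs]
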