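"""Seeded synthetic phantoms with exact ground-truth masks.

Each generator is a pure function of its parameters and seed and returns a
:class:`Phantom` (image + truth mask).  The set covers the situations the
segmenter is designed for:

* ``make_disk`` — a single bright object on a dark background;
* ``make_u_cavity`` — a bright U-shaped region (rectangle minus a
  rectangular notch), the standard concavity test that classical snakes
  fail to enter;
* ``make_notched_convex`` — a bright convex region with a darker notch
  intruding from its boundary, emulating papillary muscles inside the left
  ventricle; its ground truth is the *full* convex region, following the
  clinical convention that the ventricle outline stays convex;
* ``make_disk_volume`` — a slice stack of smoothly varying disks for
  slice-marching 3D segmentation.

Noise is additive Gaussian, clipped to [0, 1]; the default is noise-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import ImageGrid
from .volume import VolumeStack

__all__ = [
    "Phantom",
    "make_disk",
    "make_u_cavity",
    "make_notched_convex",
    "make_disk_volume",
]


@dataclass(frozen=True)
class Phantom:
    grid: ImageGrid
    truth_mask: np.ndarray  # uint8, same shape as grid
    description: str
    seed: int


def _finish(base: np.ndarray, noise_sd: float, seed: int) -> np.ndarray:
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        base = base + rng.normal(0.0, noise_sd, size=base.shape)
    return np.clip(base, 0.0, 1.0)


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float):
    ny, nx = shape
    pp, qq = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
    cx, cy = center
    return ((pp - cx) ** 2 + (qq - cy) ** 2 < radius**2).astype(np.uint8)


def make_disk(
    shape: tuple[int, int] = (128, 128),
    center: tuple[float, float] = (64.0, 64.0),
    radius: float = 20.0,
    fg: float = 1.0,
    bg: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Phantom:
    """Bright disk on a dark background; truth from the exact disk inequality.

    ``center`` is (cx, cy) in (u, v) = (x, y) pixel coordinates; a pixel
    center (p, q) is foreground iff (p-cx)^2 + (q-cy)^2 < radius^2.
    """
    if radius <= 2:
        raise ValueError("radius must exceed 2 pixels")
    if fg == bg:
        raise ValueError("fg and bg intensities must differ")
    ny, nx = shape
    cx, cy = center
    if not (cx - radius >= 0 and cx + radius <= nx - 1 and cy - radius >= 0 and cy + radius <= ny - 1):
        raise ValueError("disk extends outside the image bounds")
    truth = _disk_mask(shape, center, radius)
    img = np.where(truth.astype(bool), fg, bg).astype(float)
    grid = ImageGrid(_finish(img, noise_sd, seed), normalize=True)
    return Phantom(grid, truth, f"disk r={radius} at {center}", seed)


def make_u_cavity(
    shape: tuple[int, int] = (128, 128),
    origin: tuple[int, int] = (24, 30),
    size: tuple[int, int] = (80, 68),
    notch_width: int = 24,
    notch_depth: int = 44,
    fg: float = 1.0,
    bg: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Phantom:
    """Bright U-shaped region: a rectangle minus a top-centered notch.

    ``origin`` = (u0, v0) of the rectangle's top-left corner, ``size`` =
    (width, height) in pixels; the notch opens at the top edge (smaller v)
    and is centered horizontally.  ``notch_depth = 0`` degenerates to the
    plain rectangle.  Truth is the exact set difference of the two
    rectangle masks.
    """
    ny, nx = shape
    u0, v0 = origin
    w, h = size
    if notch_width >= w:
        raise ValueError("notch wider than the rectangle")
    if notch_depth > h:
        raise ValueError("notch deeper than the rectangle")
    if u0 < 0 or v0 < 0 or u0 + w > nx or v0 + h > ny:
        raise ValueError("rectangle extends outside the image bounds")
    rect = np.zeros(shape, dtype=np.uint8)
    rect[v0 : v0 + h, u0 : u0 + w] = 1
    notch = np.zeros(shape, dtype=np.uint8)
    nu0 = u0 + (w - notch_width) // 2
    notch[v0 : v0 + notch_depth, nu0 : nu0 + notch_width] = 1
    truth = (rect & ~notch).astype(np.uint8)
    img = np.where(truth.astype(bool), fg, bg).astype(float)
    grid = ImageGrid(_finish(img, noise_sd, seed), normalize=True)
    return Phantom(grid, truth, f"u-cavity {size} notch {notch_width}x{notch_depth}", seed)


def make_notched_convex(
    shape: tuple[int, int] = (128, 128),
    center: tuple[float, float] = (64.0, 64.0),
    radius: float = 26.0,
    notch_width: int = 28,
    notch_depth: int = 26,
    fg: float = 1.0,
    bg: float = 0.0,
    notch_intensity: float | None = 0.35,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Phantom:
    """Bright disk with a dark notch intruding from its right boundary.

    The notch (a rectangle clipped to the disk, at ``notch_intensity``)
    mimics papillary muscles: an intermediate gray, brighter than the
    background but well below the cavity, like muscle tissue next to a
    bright blood pool.  Pass ``notch_intensity=None`` for a
    background-level notch.  The truth mask is the *full* disk regardless
    of the notch: the desired outline is the convex envelope of the organ.
    ``notch_intensity = fg`` degenerates to the plain disk phantom.
    """
    if notch_intensity is None:
        notch_intensity = bg
    disk = make_disk(shape, center, radius, fg=fg, bg=bg, noise_sd=0.0, seed=seed)
    truth = disk.truth_mask
    img = np.where(truth.astype(bool), fg, bg).astype(float)
    cx, cy = center
    ny, nx = shape
    pp, qq = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
    in_notch = (
        (pp >= cx + radius - notch_depth)
        & (np.abs(qq - cy) <= notch_width / 2.0)
        & truth.astype(bool)
    )
    img[in_notch] = notch_intensity
    grid = ImageGrid(_finish(img, noise_sd, seed), normalize=True)
    return Phantom(
        grid, truth, f"notched convex r={radius} notch {notch_width}x{notch_depth}", seed
    )


def make_disk_volume(
    shape: tuple[int, int] = (128, 128),
    n_slices: int = 8,
    radius_profile=None,
    center: tuple[float, float] = (64.0, 64.0),
    fg: float = 1.0,
    bg: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[VolumeStack, np.ndarray]:
    """Stack of disk slices with a per-slice radius profile.

    ``radius_profile`` is a sequence of ``n_slices`` radii (default: all
    20 px).  Returns the stack and a (ny, nx, n_slices) uint8 truth volume;
    each slice's truth equals :func:`make_disk`'s, slice-wise.  Noise, when
    enabled, is drawn independently per slice from a per-slice seed.
    """
    if radius_profile is None:
        radius_profile = [20.0] * n_slices
    radii = [float(r) for r in radius_profile]
    if len(radii) != n_slices:
        raise ValueError("radius_profile length must equal n_slices")
    slices, truths = [], []
    for i, r in enumerate(radii):
        ph = make_disk(shape, center, r, fg=fg, bg=bg, noise_sd=noise_sd, seed=seed + i)
        slices.append(ph.grid)
        truths.append(ph.truth_mask)
    stack = VolumeStack(slices=slices, slice_spacing=1.0)
    return stack, np.stack(truths, axis=-1)
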