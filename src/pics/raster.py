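"""Polygon-to-mask rasterization and region statistics.

The characteristic function chi of the contour is obtained by an even-odd
(crossing-number) point-in-polygon test applied to every pixel center, with
the polygon taken directly through the control knots.  Pixel (p, q) has its
center at continuous coordinates (u, v) = (p, q), 0-based; the image array
is indexed ``[q, p]`` (row-major, shape N_y x N_x).

Boundary rule: a pixel center lying exactly on a polygon edge counts as
*outside* (strict interior).  This makes the rasterization deterministic
and independent of edge direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = [
    "ImageGrid",
    "RegionStats",
    "CollapsedContourError",
    "normalize_intensities",
    "rasterize_polygon",
    "region_means",
    "polygon_is_simple",
]


class CollapsedContourError(RuntimeError):
    """The contour encloses no pixel centers (snake shrank to nothing)."""


def normalize_intensities(arr: np.ndarray) -> np.ndarray:
    """Min-max normalize an array to [0, 1]; a constant image maps to zeros."""
    a = np.asarray(arr, dtype=float)
    lo, hi = float(a.min()), float(a.max())
    if hi > lo:
        return (a - lo) / (hi - lo)
    return np.zeros_like(a)


class ImageGrid:
    """A 2D grayscale image on the pixel grid, normalized to [0, 1].

    Caches the quantities the region energy needs repeatedly: the squared
    gradient magnitude (centered differences, one-sided at borders) and
    whole-image intensity sums.
    """

    def __init__(self, intensities: np.ndarray, normalize: bool = True):
        a = np.asarray(intensities, dtype=float)
        if a.ndim != 2:
            raise ValueError(f"image must be 2D, got shape {a.shape}")
        if a.shape[0] < 8 or a.shape[1] < 8:
            raise ValueError(f"image must be at least 8x8, got {a.shape}")
        if not np.all(np.isfinite(a)):
            raise ValueError("image intensities must be finite")
        if normalize:
            a = normalize_intensities(a)
        elif a.min() < 0.0 or a.max() > 1.0:
            raise ValueError("intensities outside [0, 1]; pass normalize=True")
        self.intensities = a

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    @cached_property
    def grad_sq(self) -> np.ndarray:
        """|grad I|^2 via centered differences (one-sided at borders)."""
        gy, gx = np.gradient(self.intensities)
        return gx**2 + gy**2

    @cached_property
    def sum_i(self) -> float:
        return float(self.intensities.sum())

    @cached_property
    def sum_i2(self) -> float:
        return float((self.intensities**2).sum())


@dataclass(frozen=True)
class RegionStats:
    """Mean intensity and pixel count inside / outside the contour."""

    mu_in: float
    mu_out: float
    n_in: int
    n_out: int


def polygon_is_simple(knots: np.ndarray) -> bool:
    """True if no two non-adjacent polygon edges properly intersect."""
    pts = np.asarray(knots, dtype=float)
    n = pts.shape[0]
    a = pts
    b = np.roll(pts, -1, axis=0)

    def orient(p, q, r):
        return (q[..., 0] - p[..., 0]) * (r[..., 1] - p[..., 1]) - (
            q[..., 1] - p[..., 1]
        ) * (r[..., 0] - p[..., 0])

    i_idx, j_idx = np.triu_indices(n, k=2)
    # exclude the wrap-around adjacency (edge 0 with edge n-1)
    keep = ~((i_idx == 0) & (j_idx == n - 1))
    i_idx, j_idx = i_idx[keep], j_idx[keep]
    p1, p2 = a[i_idx], b[i_idx]
    p3, p4 = a[j_idx], b[j_idx]
    d1 = orient(p3, p4, p1)
    d2 = orient(p3, p4, p2)
    d3 = orient(p1, p2, p3)
    d4 = orient(p1, p2, p4)
    proper = (d1 * d2 < 0) & (d3 * d4 < 0)
    return not bool(np.any(proper))


def _point_in_polygon(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd crossing test with strict-interior boundary rule.

    ``px``, ``py`` are flat arrays of query coordinates; returns a boolean
    array.  Points exactly on an edge are classified outside.
    """
    x1 = poly[:, 0]
    y1 = poly[:, 1]
    x2 = np.roll(x1, -1)
    y2 = np.roll(y1, -1)

    pyc = py[:, None]
    pxc = px[:, None]
    # horizontal ray to +x: edge straddles the scanline (half-open in y)
    straddle = (y1 > pyc) != (y2 > pyc)
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = x1 + (pyc - y1) * (x2 - x1) / (y2 - y1)
    crossings = np.sum(straddle & (pxc < xint), axis=1)
    inside = (crossings % 2) == 1

    # strict interior: force points on any edge to outside
    ex, ey = x2 - x1, y2 - y1
    cross = ex * (pyc - y1) - ey * (pxc - x1)
    scale = np.maximum(np.hypot(ex, ey), 1e-300)
    on_line = np.abs(cross) / scale <= 1e-9
    in_box = (
        (pxc >= np.minimum(x1, x2) - 1e-9)
        & (pxc <= np.maximum(x1, x2) + 1e-9)
        & (pyc >= np.minimum(y1, y2) - 1e-9)
        & (pyc <= np.maximum(y1, y2) + 1e-9)
    )
    on_edge = np.any(on_line & in_box, axis=1)
    return inside & ~on_edge


def rasterize_polygon(
    knots: np.ndarray,
    grid_shape: tuple[int, int],
    check_simple: bool = True,
) -> np.ndarray:
    """Characteristic function of the knot polygon on the pixel grid.

    Returns a uint8 array of shape ``grid_shape`` (N_y, N_x) with 1 at every
    pixel center strictly inside the polygon under the even-odd rule.

    A self-intersecting polygon triggers a warning but is still filled by
    the even-odd rule: transient self-intersections can occur mid-descent
    and must not abort an optimization run.  Pass ``check_simple=False`` to
    skip the (quadratic in edge count) simplicity test in hot loops.
    """
    pts = np.asarray(knots, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("polygon needs an (N>=3, 2) vertex array")
    ny, nx = int(grid_shape[0]), int(grid_shape[1])
    if nx < 1 or ny < 1:
        raise ValueError(f"invalid grid shape {grid_shape}")
    if check_simple and not polygon_is_simple(pts):
        warnings.warn(
            "self-intersecting polygon: filling by the even-odd rule",
            RuntimeWarning,
            stacklevel=2,
        )

    # only pixel centers within the polygon bounding box can be inside
    p_lo = max(int(np.ceil(pts[:, 0].min())), 0)
    p_hi = min(int(np.floor(pts[:, 0].max())), nx - 1)
    q_lo = max(int(np.ceil(pts[:, 1].min())), 0)
    q_hi = min(int(np.floor(pts[:, 1].max())), ny - 1)
    chi = np.zeros((ny, nx), dtype=np.uint8)
    if p_hi < p_lo or q_hi < q_lo:
        return chi

    pp, qq = np.meshgrid(
        np.arange(p_lo, p_hi + 1, dtype=float),
        np.arange(q_lo, q_hi + 1, dtype=float),
    )
    inside = _point_in_polygon(pp.ravel(), qq.ravel(), pts)
    chi[q_lo : q_hi + 1, p_lo : p_hi + 1] = inside.reshape(pp.shape)
    return chi


def region_means(grid: ImageGrid, mask: np.ndarray) -> RegionStats:
    """Mean intensity inside (chi=1) and outside (chi=0) the contour.

    Raises :class:`CollapsedContourError` when the mask is empty — the
    optimizer treats that as a failed step.  An all-ones mask is degenerate
    but allowed, with ``mu_out`` defined as 0.
    """
    chi = np.asarray(mask)
    if chi.shape != grid.shape:
        raise ValueError(f"mask shape {chi.shape} != image shape {grid.shape}")
    chi_b = chi.astype(bool)
    n_in = int(chi_b.sum())
    n_total = chi_b.size
    n_out = n_total - n_in
    if n_in == 0:
        raise CollapsedContourError("contour encloses no pixel centers")
    sum_in = float(grid.intensities[chi_b].sum())
    mu_in = sum_in / n_in
    mu_out = (grid.sum_i - sum_in) / n_out if n_out > 0 else 0.0
    return RegionStats(mu_in=mu_in, mu_out=mu_out, n_in=n_in, n_out=n_out)
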