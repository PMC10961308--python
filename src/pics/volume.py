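"""3D segmentation by slice marching with transferred knot initializations.

A volume is segmented slice by slice: the first slice starts from a small
circle of knots around a user seed point; every later slice starts from the
previous slice's converged knots ("spatially aware initialization").  The
discrete update ``w[n] = w_opt[n-1] + F(I[n], w_opt[n-1])`` is the
time-marching view of contour propagation through the stack; no separate
ODE integrator is involved.  Knot count — and hence the trainable
parameter count — is conserved across slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import ImageGrid

__all__ = ["VolumeStack", "init_circle", "segment_volume"]


@dataclass(frozen=True)
class VolumeStack:
    """Ordered slices of identical shape; spacing is metadata only."""

    slices: list[ImageGrid]
    slice_spacing: float = 1.0

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise ValueError("a volume needs at least one slice")
        shapes = {g.shape for g in self.slices}
        if len(shapes) != 1:
            raise ValueError(f"slices differ in shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices[0].shape

    def __len__(self) -> int:
        return len(self.slices)

    def as_array(self) -> np.ndarray:
        """(ny, nx, n_slices) float array of the normalized intensities."""
        return np.stack([g.intensities for g in self.slices], axis=-1)


def init_circle(
    center: tuple[float, float],
    radius: float,
    n_knots: int,
    grid_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Knots evenly spaced on a circle, counter-clockwise from angle 0.

    ``center`` is (cx, cy) in (u, v) coordinates.  With a ``grid_shape``
    given, the circle must lie fully inside the image bounds.  This is the
    canonical snake initialization from a single user click; 10 knots in
    2D expose 20 trainable parameters.
    """
    if radius <= 0:
        raise ValueError("initialization radius must be positive")
    if n_knots < 4:
        raise ValueError("need at least 4 knots")
    cx, cy = float(center[0]), float(center[1])
    if grid_shape is not None:
        ny, nx = grid_shape
        if cx - radius < 0 or cx + radius > nx - 1 or cy - radius < 0 or cy + radius > ny - 1:
            raise ValueError(
                f"initial circle (center ({cx}, {cy}), r={radius}) exits image bounds"
            )
    # counter-clockwise in (u, v): angle increases from +u toward +v
    ang = 2.0 * np.pi * np.arange(n_knots) / n_knots
    return np.stack([cx + radius * np.cos(ang), cy + radius * np.sin(ang)], axis=1)


def segment_volume(stack, seed_xy, weights, config, **kwargs):
    """Functional wrapper over :class:`pics.estimators.VolumeSegmenter`.

    Returns the fitted estimator; per-slice knots, masks and histories are
    on its ``knots_``, ``masks_`` and ``histories_`` attributes.
    """
    from .estimators import VolumeSegmenter

    est = VolumeSegmenter(
        **{**_params_from(weights, config), **kwargs}
    )
    return est.fit(stack, seed_xy=seed_xy)


def _params_from(weights, config) -> dict:
    from dataclasses import asdict

    p = asdict(weights)
    p.update(asdict(config))
    return p
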