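"""Every term of the snake objective and its weighted total.

The objective combines

* membrane energy  J_psi_s  = (1/N) sum_i (u_s^2 + v_s^2)_i        (first
  parametric derivative at the knots),
* bending energy   J_psi_ss = (1/N) sum_i (u_ss^2 + v_ss^2)_i      (second
  derivative),
* Chan-Vese region energy J_cv: an unnormalized pixel sum of
  ((I - mu_in) chi)^2 + gamma (|grad I| chi)^2 + ((I - mu_out)(1 - chi))^2,
* an optional convexity prior J_shape = (1/N) sum_i kappa_i^2.

Total: J = alpha J_psi_s + beta J_psi_ss + mu J_cv + sigma J_shape, with
J_int = alpha J_psi_s + beta J_psi_ss and J_ext = mu J_cv.  The knot
average in the internal/shape terms and the raw pixel sum in J_cv are kept
exactly as stated so the shipped coefficient presets keep their magnitudes.

The gradient term inside J_cv uses the squared gradient magnitude
(I_x^2 + I_y^2) from centered differences, one-sided at image borders;
it penalizes intensity variation inside the contour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import ImageGrid, RegionStats, rasterize_polygon, region_means
from .spline import (
    KnotDerivatives,
    curvature_at_knots,
    derivatives_at_knots,
    fit_periodic_cubic,
)

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "internal_energy",
    "chan_vese_energy",
    "shape_prior_energy",
    "total_loss",
]


@dataclass(frozen=True)
class LossWeights:
    """Coefficients of the objective.

    alpha: membrane (first-derivative) coefficient
    beta:  bending (second-derivative) coefficient
    mu:    Chan-Vese region coefficient (the one OPI adapts)
    gamma: gradient-uniformity coefficient inside J_cv
    sigma: convexity-prior coefficient
    """

    alpha: float
    beta: float
    mu: float
    gamma: float = 0.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "mu", "gamma", "sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def replace(self, **kwargs) -> "LossWeights":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass(frozen=True)
class LossBreakdown:
    """Raw energy terms plus the weighted internal/external/total values."""

    j_psi_s: float
    j_psi_ss: float
    j_cv: float
    j_shape: float  # raw (1/N) sum kappa^2; sigma applied in `total`
    j_int: float
    j_ext: float
    total: float

    @classmethod
    def from_terms(
        cls,
        j_psi_s: float,
        j_psi_ss: float,
        j_cv: float,
        j_shape: float,
        weights: LossWeights,
    ) -> "LossBreakdown":
        j_int = weights.alpha * j_psi_s + weights.beta * j_psi_ss
        j_ext = weights.mu * j_cv
        return cls(
            j_psi_s=j_psi_s,
            j_psi_ss=j_psi_ss,
            j_cv=j_cv,
            j_shape=j_shape,
            j_int=j_int,
            j_ext=j_ext,
            total=j_int + j_ext + weights.sigma * j_shape,
        )


def internal_energy(deriv: KnotDerivatives) -> tuple[float, float]:
    """Membrane and bending energies: knot averages of squared derivatives."""
    j_s = float(np.mean(deriv.du_ds**2 + deriv.dv_ds**2))
    j_ss = float(np.mean(deriv.d2u_ds2**2 + deriv.d2v_ds2**2))
    return j_s, j_ss


def chan_vese_energy(
    grid: ImageGrid,
    mask: np.ndarray,
    stats: RegionStats,
    gamma: float = 0.0,
) -> float:
    """Region energy: intensity variance about the two region means.

    ``stats`` must come from the same (grid, mask) pair.  The outside term
    is accumulated through whole-image sums so only pixels inside the
    contour are touched — the contour bounding box is usually a small part
    of the image and this is the optimizer's innermost loop.
    """
    chi = np.asarray(mask)
    if chi.shape != grid.shape:
        raise ValueError(f"mask shape {chi.shape} != image shape {grid.shape}")
    chi_b = chi.astype(bool)
    i_in = grid.intensities[chi_b]
    sum_in = float(i_in.sum())
    sum_in2 = float((i_in**2).sum())
    n_in = i_in.size
    term_in = sum_in2 - 2.0 * stats.mu_in * sum_in + stats.mu_in**2 * n_in
    term_grad = gamma * float(grid.grad_sq[chi_b].sum()) if gamma != 0.0 else 0.0
    n_out = chi_b.size - n_in
    term_out = (
        (grid.sum_i2 - sum_in2)
        - 2.0 * stats.mu_out * (grid.sum_i - sum_in)
        + stats.mu_out**2 * n_out
    )
    # each term is a sum of squares; clip the tiny negative rounding residue
    return max(term_in, 0.0) + term_grad + max(term_out, 0.0)


def shape_prior_energy(kappa: np.ndarray) -> float:
    """Raw convexity prior: knot average of squared curvature."""
    return float(np.mean(np.asarray(kappa, dtype=float) ** 2))


def total_loss(
    knots: np.ndarray,
    grid: ImageGrid,
    weights: LossWeights,
) -> LossBreakdown:
    """Full objective at the given knot configuration.

    Pure function of its inputs: fits the periodic spline, rasterizes the
    knot polygon, computes region statistics and all energy terms.
    Propagates degenerate-geometry and collapsed-contour errors.
    """
    model = fit_periodic_cubic(knots)
    deriv = derivatives_at_knots(model)
    j_s, j_ss = internal_energy(deriv)
    j_shape = shape_prior_energy(curvature_at_knots(deriv))
    mask = rasterize_polygon(knots, grid.shape, check_simple=False)
    stats = region_means(grid, mask)
    j_cv = chan_vese_energy(grid, mask, stats, gamma=weights.gamma)
    return LossBreakdown.from_terms(j_s, j_ss, j_cv, j_shape, weights)
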