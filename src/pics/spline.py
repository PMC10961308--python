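"""Closed periodic cubic splines through contour control knots.

The contour hypothesis is a closed curve interpolated by N local cubic
segments, one per pair of consecutive knots, with a local parameter
``s in [0, 1]`` on each segment (uniform parametrization, unit knot
spacing).  The knots themselves are the trainable weights of the snake;
everything here is exact double-precision linear algebra, no fitting.

Coordinate convention: a knot is a pair ``(u, v)`` where ``u`` is the
continuous x (column) coordinate and ``v`` the y (row) coordinate of the
pixel frame.  Knot sequences are cyclic: knot N-1 connects back to knot 0.

Curvature sign convention: for a contour traversed counter-clockwise in
the (u, v) plane, a convex contour has positive curvature at every knot
(kappa = (v_ss*u_s - u_ss*v_s) / (u_s^2 + v_s^2)^(3/2)).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "SplineModel",
    "KnotDerivatives",
    "validate_knots",
    "ensure_ccw",
    "fit_periodic_cubic",
    "evaluate_segment",
    "evaluate_dense",
    "derivatives_at_knots",
    "curvature_at_knots",
    "signed_area",
]


class DegenerateGeometryError(ValueError):
    """Contour geometry that makes downstream quantities undefined."""


@dataclass(frozen=True)
class SplineModel:
    """Per-segment cubic coefficients of a closed periodic spline.

    Segment ``i`` maps local ``s in [0, 1]`` to
    ``u_i(s) = a s^3 + b s^2 + c s + d`` and
    ``v_i(s) = e s^3 + f s^2 + g s + h``,
    with ``s = 0`` at knot ``i`` and ``s = 1`` at knot ``i + 1`` (cyclic).
    """

    coeff_u: np.ndarray  # (N, 4) rows [a, b, c, d]
    coeff_v: np.ndarray  # (N, 4) rows [e, f, g, h]

    @property
    def n_segments(self) -> int:
        return self.coeff_u.shape[0]


@dataclass(frozen=True)
class KnotDerivatives:
    """Parametric spline derivatives evaluated at the knots."""

    du_ds: np.ndarray
    dv_ds: np.ndarray
    d2u_ds2: np.ndarray
    d2v_ds2: np.ndarray


def validate_knots(knots: np.ndarray) -> np.ndarray:
    """Validate and return control knots as a float (N, 2) array.

    Requires N >= 4, finite coordinates, and no two consecutive knots
    coincident (a zero-length segment leaves curvature undefined).
    """
    pts = np.asarray(knots, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"knots must be an (N, 2) array, got shape {pts.shape}")
    if pts.shape[0] < 4:
        raise ValueError(f"need at least 4 control knots, got {pts.shape[0]}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("knot coordinates must be finite")
    gaps = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    if np.any(gaps == 0.0):
        i = int(np.argmin(gaps))
        raise DegenerateGeometryError(
            f"consecutive duplicate knots at index {i} (zero-length segment)"
        )
    return pts


def signed_area(knots: np.ndarray) -> float:
    """Shoelace signed area of the knot polygon (positive for CCW in (u, v))."""
    pts = np.asarray(knots, dtype=float)
    u, v = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(u * np.roll(v, -1) - np.roll(u, -1) * v))


def ensure_ccw(knots: np.ndarray) -> np.ndarray:
    """Canonicalize knot order to counter-clockwise traversal.

    Applied once at ingest so the curvature sign convention is stable;
    a zero signed area is left untouched (orientation undefined).
    """
    pts = np.asarray(knots, dtype=float)
    if signed_area(pts) < 0.0:
        return pts[::-1].copy()
    return pts.copy()


@lru_cache(maxsize=32)
def _cyclic_system_inverse(n: int) -> np.ndarray:
    """Inverse of the cyclic tridiagonal matrix diag(1, 4, 1) of size n.

    The matrix is strictly diagonally dominant, hence well conditioned;
    caching its inverse per knot count removes the dominant cost from the
    optimizer's finite-difference inner loop.
    """
    A = 4.0 * np.eye(n)
    idx = np.arange(n)
    A[idx, (idx + 1) % n] = 1.0
    A[idx, (idx - 1) % n] = 1.0
    return np.linalg.inv(A)


def _periodic_second_derivatives(y: np.ndarray) -> np.ndarray:
    """Solve the cyclic tridiagonal system for knot second derivatives.

    With unit knot spacing the C2 conditions reduce to
    ``M[i-1] + 4 M[i] + M[i+1] = 6 (y[i+1] - 2 y[i] + y[i-1])`` cyclically.
    """
    rhs = 6.0 * (np.roll(y, -1) - 2.0 * y + np.roll(y, 1))
    return _cyclic_system_inverse(y.shape[0]) @ rhs


def _coeffs_from_moments(y: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Per-segment cubic coefficients [a, b, c, d] from knot values/moments."""
    y_next = np.roll(y, -1)
    m_next = np.roll(m, -1)
    a = (m_next - m) / 6.0
    b = m / 2.0
    c = (y_next - y) - (2.0 * m + m_next) / 6.0
    d = y
    return np.stack([a, b, c, d], axis=1)


def fit_periodic_cubic(knots: np.ndarray) -> SplineModel:
    """Fit the closed C2 periodic cubic spline interpolating the knots.

    Solves the cyclic tridiagonal system for the knot second derivatives
    of each coordinate, then converts to per-segment cubic coefficients.
    The system is well-posed (strictly diagonally dominant) for any valid
    knot set, so the solve is deterministic with a unique solution.
    """
    pts = validate_knots(knots)
    u, v = pts[:, 0], pts[:, 1]
    mu = _periodic_second_derivatives(u)
    mv = _periodic_second_derivatives(v)
    return SplineModel(_coeffs_from_moments(u, mu), _coeffs_from_moments(v, mv))


def evaluate_segment(
    model: SplineModel, segment: int, s: np.ndarray | float, order: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate (u, v) or a parametric derivative on one segment.

    ``order`` 0/1/2 selects the curve, first, or second s-derivative.
    """
    s = np.asarray(s, dtype=float)
    cu = model.coeff_u[segment]
    cv = model.coeff_v[segment]
    if order == 0:
        u = ((cu[0] * s + cu[1]) * s + cu[2]) * s + cu[3]
        v = ((cv[0] * s + cv[1]) * s + cv[2]) * s + cv[3]
    elif order == 1:
        u = (3.0 * cu[0] * s + 2.0 * cu[1]) * s + cu[2]
        v = (3.0 * cv[0] * s + 2.0 * cv[1]) * s + cv[2]
    elif order == 2:
        u = 6.0 * cu[0] * s + 2.0 * cu[1]
        v = 6.0 * cv[0] * s + 2.0 * cv[1]
    else:
        raise ValueError("order must be 0, 1 or 2")
    return u, v


def evaluate_dense(model: SplineModel, samples_per_segment: int = 20) -> np.ndarray:
    """Sample the full closed curve, ``samples_per_segment`` points per segment.

    Returns an (N * samples_per_segment, 2) array; the closing point (s=1 of
    the last segment, equal to the first knot) is not duplicated.
    """
    s = np.arange(samples_per_segment) / samples_per_segment
    pts = []
    for i in range(model.n_segments):
        u, v = evaluate_segment(model, i, s)
        pts.append(np.stack([u, v], axis=1))
    return np.concatenate(pts, axis=0)


def derivatives_at_knots(model: SplineModel) -> KnotDerivatives:
    """First/second parametric derivatives of the spline at each knot.

    The value at knot ``i`` is the (common) one-sided limit from the two
    adjacent segments; C2 continuity makes the limits equal, which is
    asserted rather than assumed.
    """
    n = model.n_segments
    # right limit: s=0 of segment i
    du_r = model.coeff_u[:, 2]
    dv_r = model.coeff_v[:, 2]
    d2u_r = 2.0 * model.coeff_u[:, 1]
    d2v_r = 2.0 * model.coeff_v[:, 1]
    # left limit: s=1 of segment i-1
    prev = np.arange(-1, n - 1)
    cu, cv = model.coeff_u[prev], model.coeff_v[prev]
    du_l = 3.0 * cu[:, 0] + 2.0 * cu[:, 1] + cu[:, 2]
    dv_l = 3.0 * cv[:, 0] + 2.0 * cv[:, 1] + cv[:, 2]
    d2u_l = 6.0 * cu[:, 0] + 2.0 * cu[:, 1]
    d2v_l = 6.0 * cv[:, 0] + 2.0 * cv[:, 1]

    scale = 1.0 + np.max(np.abs(np.concatenate([du_r, dv_r, d2u_r, d2v_r])))
    for left, right in ((du_l, du_r), (dv_l, dv_r), (d2u_l, d2u_r), (d2v_l, d2v_r)):
        mism = np.max(np.abs(left - right)) / scale
        if mism > 1e-8:
            raise AssertionError(
                f"junction derivative mismatch {mism:.2e}: spline is not C2"
            )
    return KnotDerivatives(du_r, dv_r, d2u_r, d2v_r)


def derivatives_from_knots(knots: np.ndarray) -> KnotDerivatives:
    """Knot derivatives straight from knot positions, skipping validation.

    Equivalent to ``derivatives_at_knots(fit_periodic_cubic(knots))`` but
    without coefficient assembly or the C2 assertion — the optimizer's
    finite-difference loop calls this thousands of times per run.
    """
    pts = np.asarray(knots, dtype=float)
    u, v = pts[:, 0], pts[:, 1]
    mu_ = _periodic_second_derivatives(u)
    mv_ = _periodic_second_derivatives(v)
    du = (np.roll(u, -1) - u) - (2.0 * mu_ + np.roll(mu_, -1)) / 6.0
    dv = (np.roll(v, -1) - v) - (2.0 * mv_ + np.roll(mv_, -1)) / 6.0
    return KnotDerivatives(du, dv, mu_, mv_)


def curvature_at_knots(deriv: KnotDerivatives) -> np.ndarray:
    """Signed curvature at each knot.

    kappa = (v_ss * u_s - u_ss * v_s) / (u_s^2 + v_s^2)^(3/2); positive for
    a convex contour traversed counter-clockwise.  A vanishing tangent at a
    knot leaves curvature undefined and raises.
    """
    speed_sq = deriv.du_ds**2 + deriv.dv_ds**2
    if np.any(speed_sq <= 0.0) or not np.all(np.isfinite(speed_sq)):
        raise DegenerateGeometryError("vanishing tangent: curvature undefined")
    num = deriv.d2v_ds2 * deriv.du_ds - deriv.d2u_ds2 * deriv.dv_ds
    return num / speed_sq**1.5
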