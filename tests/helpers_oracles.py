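"""Independent brute-force oracles used by the test suite.

Everything here deliberately re-derives results through a different route
than the package: a dense 4N-per-coordinate linear system for the periodic
spline (instead of the cyclic moment system), per-pixel python loops for
rasterization, region statistics and the region energy (instead of the
vectorized implementations).
"""

from __future__ import annotations

import numpy as np


def dense_periodic_spline_coeffs(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve the full continuity/smoothness/periodicity system densely.

    For each coordinate the unknowns are the 4N cubic coefficients
    [a_i, b_i, c_i, d_i]; the equations are, per segment i (cyclic):
    value at s=0, value at s=1, first- and second-derivative continuity at
    the junction with segment i+1.  Returns (coeff_u, coeff_v), each (N, 4).
    """
    pts = np.asarray(knots, dtype=float)
    n = pts.shape[0]

    def solve_coord(y: np.ndarray) -> np.ndarray:
        A = np.zeros((4 * n, 4 * n))
        b = np.zeros(4 * n)
        for i in range(n):
            j = (i + 1) % n
            r = 4 * i
            # value at s=0 equals knot i
            A[r, 4 * i + 3] = 1.0
            b[r] = y[i]
            # value at s=1 equals knot i+1
            A[r + 1, 4 * i : 4 * i + 4] = [1.0, 1.0, 1.0, 1.0]
            b[r + 1] = y[j]
            # first derivative continuity: 3a_i + 2b_i + c_i - c_j = 0
            A[r + 2, 4 * i : 4 * i + 3] = [3.0, 2.0, 1.0]
            A[r + 2, 4 * j + 2] -= 1.0
            # second derivative continuity: 6a_i + 2b_i - 2b_j = 0
            A[r + 3, 4 * i] = 6.0
            A[r + 3, 4 * i + 1] = 2.0
            A[r + 3, 4 * j + 1] -= 2.0
        return np.linalg.solve(A, b).reshape(n, 4)

    return solve_coord(pts[:, 0]), solve_coord(pts[:, 1])


def dense_knot_derivatives(knots: np.ndarray):
    """Analytic knot derivatives from the dense coefficient solve."""
    cu, cv = dense_periodic_spline_coeffs(knots)
    return cu[:, 2], cv[:, 2], 2.0 * cu[:, 1], 2.0 * cv[:, 1]


def point_in_polygon_loop(px: float, py: float, poly: np.ndarray) -> bool:
    """Scalar even-odd ray-cast with the strict-interior boundary rule."""
    n = len(poly)
    crossings = 0
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        # on-edge check: outside by the strict rule
        ex, ey = x2 - x1, y2 - y1
        norm = max((ex * ex + ey * ey) ** 0.5, 1e-300)
        if abs(ex * (py - y1) - ey * (px - x1)) / norm <= 1e-9:
            if (
                min(x1, x2) - 1e-9 <= px <= max(x1, x2) + 1e-9
                and min(y1, y2) - 1e-9 <= py <= max(y1, y2) + 1e-9
            ):
                return False
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                crossings += 1
    return crossings % 2 == 1


def rasterize_loop(poly: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    ny, nx = shape
    chi = np.zeros((ny, nx), dtype=np.uint8)
    for q in range(ny):
        for p in range(nx):
            chi[q, p] = point_in_polygon_loop(float(p), float(q), poly)
    return chi


def region_means_loop(image: np.ndarray, chi: np.ndarray):
    s_in = n_in = s_out = n_out = 0.0
    ny, nx = image.shape
    for q in range(ny):
        for p in range(nx):
            if chi[q, p]:
                s_in += image[q, p]
                n_in += 1
            else:
                s_out += image[q, p]
                n_out += 1
    mu_in = s_in / n_in if n_in else 0.0
    mu_out = s_out / n_out if n_out else 0.0
    return mu_in, mu_out, int(n_in), int(n_out)


def grad_sq_loop(image: np.ndarray) -> np.ndarray:
    """Squared gradient magnitude: centered differences, one-sided at borders."""
    ny, nx = image.shape
    g = np.zeros((ny, nx))
    for q in range(ny):
        for p in range(nx):
            if 0 < p < nx - 1:
                gx = (image[q, p + 1] - image[q, p - 1]) / 2.0
            elif p == 0:
                gx = image[q, 1] - image[q, 0]
            else:
                gx = image[q, nx - 1] - image[q, nx - 2]
            if 0 < q < ny - 1:
                gy = (image[q + 1, p] - image[q - 1, p]) / 2.0
            elif q == 0:
                gy = image[1, p] - image[0, p]
            else:
                gy = image[ny - 1, p] - image[ny - 2, p]
            g[q, p] = gx * gx + gy * gy
    return g


def chan_vese_loop(image: np.ndarray, chi: np.ndarray, gamma: float) -> float:
    mu_in, mu_out, _, _ = region_means_loop(image, chi)
    gsq = grad_sq_loop(image)
    total = 0.0
    ny, nx = image.shape
    for q in range(ny):
        for p in range(nx):
            c = float(chi[q, p])
            total += ((image[q, p] - mu_in) * c) ** 2
            total += gamma * gsq[q, p] * c * c
            total += ((image[q, p] - mu_out) * (1.0 - c)) ** 2
    return total


def total_loss_composed(knots: np.ndarray, image: np.ndarray, alpha, beta, mu,
                        gamma, sigma) -> float:
    """Full objective recomputed by composing the brute-force oracles."""
    du, dv, d2u, d2v = dense_knot_derivatives(knots)
    n = len(knots)
    j_s = float(np.sum(du**2 + dv**2)) / n
    j_ss = float(np.sum(d2u**2 + d2v**2)) / n
    kappa = (d2v * du - d2u * dv) / (du**2 + dv**2) ** 1.5
    j_shape = float(np.sum(kappa**2)) / n
    chi = rasterize_loop(knots, image.shape)
    j_cv = chan_vese_loop(image, chi, gamma)
    return alpha * j_s + beta * j_ss + mu * j_cv + sigma * j_shape


def random_star_polygon(rng: np.random.Generator, n_vertices: int,
                        center: tuple[float, float], r_min: float, r_max: float
                        ) -> np.ndarray:
    """A random simple (star-shaped) polygon around ``center``.

    Angular gaps are bounded away from pi (each edge stays inside its
    angular wedge), which guarantees simplicity for any radii.
    """
    gaps = rng.uniform(0.4, 1.0, n_vertices)
    ang = 2.0 * np.pi * np.cumsum(gaps) / gaps.sum()
    rad = rng.uniform(r_min, r_max, n_vertices)
    cx, cy = center
    return np.stack([cx + rad * np.cos(ang), cy + rad * np.sin(ang)], axis=1)
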