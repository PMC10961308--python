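"""Scikit-learn style estimators wrapping the contour optimization loop.

:class:`ContourSegmenter` fits one closed spline contour to one 2D image;
:class:`VolumeSegmenter` marches a contour through a slice stack, reusing
each converged contour as the next slice's initialization.  Both follow
the sklearn conventions — constructor hyperparameters, ``fit`` producing
trailing-underscore attributes, ``get_params``/``set_params`` — so they
compose with sklearn model selection (``score`` returns the Dice overlap
against a reference mask).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .losses import LossBreakdown, LossWeights, total_loss
from .optim import (
    OptimizerState,
    TrainingConfig,
    adam_step,
    adapt_mu,
    compute_opi,
    loss_gradient_fd,
)
from .raster import CollapsedContourError, ImageGrid, rasterize_polygon
from .spline import ensure_ccw, signed_area, validate_knots
from .volume import VolumeStack, init_circle

__all__ = ["ContourSegmenter", "VolumeSegmenter", "run_segmentation"]

_HISTORY_COLUMNS = [
    "k",
    "j_psi_s",
    "j_psi_ss",
    "j_cv",
    "j_shape",
    "j_int",
    "j_ext",
    "total",
    "opi",
    "mu",
    "area",
]


def _as_grid(image) -> ImageGrid:
    return image if isinstance(image, ImageGrid) else ImageGrid(np.asarray(image))


class ContourSegmenter(BaseEstimator):
    """Label-free single-object segmentation by spline-contour descent.

    The contour is a closed periodic cubic spline whose control knots are
    the trainable parameters (a 10-knot contour has 20 of them).  ``fit``
    minimizes ``alpha*J_psi_s + beta*J_psi_ss + mu*J_cv + sigma*J_shape``
    with central-difference gradients and Adam, monitors the OPI health
    index, and (optionally) raises ``mu`` adaptively whenever OPI leaves
    the healthy band.

    Parameters
    ----------
    alpha, beta : float
        Membrane and bending coefficients of the internal energy.
    mu : float
        Initial Chan-Vese region coefficient (adapted during the run when
        ``adaptive_mu``).
    gamma : float
        Gradient-uniformity coefficient inside the region energy.
    sigma : float
        Convexity-prior coefficient; 0 disables the shape term.
    n_knots, init_radius : int, float
        Circle initialization around the seed point passed to ``fit``.
    learning_rate, fd_step : float
        Adam base step and central-difference step, both in pixels.
        ``fd_step`` must be large enough to flip pixel memberships
        (default 1.0) because the region term is piecewise constant in
        the knot positions.
    max_iters, convergence_tol, convergence_window : int, float, int
        The run stops at ``max_iters`` or once the mean knot displacement
        stays below ``convergence_tol`` pixels for ``convergence_window``
        consecutive iterations.
    opi_window, opi_threshold, mu_cap_ratio, adaptive_mu, opi_convention
        OPI monitoring and mu adaptation; see :mod:`pics.optim`.
    seed : int
        Reserved for randomized variants; the core loop is deterministic.

    Attributes
    ----------
    knots_ : (n_knots, 2) ndarray — converged control knots (u, v).
    mask_ : (ny, nx) uint8 — characteristic function of the final contour.
    history_ : DataFrame — per-iteration energies, OPI and mu.
    n_iter_ : int; converged_ : bool; failed_ : bool (contour collapsed,
        best-so-far knots returned); mu_ : float — final region weight.
    loss_ : LossBreakdown at the final knots.
    """

    def __init__(
        self,
        alpha: float = 1e-1,
        beta: float = 1e-2,
        mu: float = 1e3,
        gamma: float = 0.0,
        sigma: float = 0.0,
        n_knots: int = 16,
        init_radius: float = 8.0,
        learning_rate: float = 0.5,
        fd_step: float = 1.0,
        max_iters: int = 500,
        opi_window: int = 10,
        opi_threshold: float = 0.8,
        mu_cap_ratio: float = 1e4,
        adam_beta1: float = 0.9,
        adam_beta2: float = 0.999,
        adam_eps: float = 1e-8,
        convergence_tol: float = 0.05,
        convergence_window: int = 10,
        adaptive_mu: bool = True,
        opi_convention: str = "as-printed",
        seed: int = 0,
    ):
        self.alpha = alpha
        self.beta = beta
        self.mu = mu
        self.gamma = gamma
        self.sigma = sigma
        self.n_knots = n_knots
        self.init_radius = init_radius
        self.learning_rate = learning_rate
        self.fd_step = fd_step
        self.max_iters = max_iters
        self.opi_window = opi_window
        self.opi_threshold = opi_threshold
        self.mu_cap_ratio = mu_cap_ratio
        self.adam_beta1 = adam_beta1
        self.adam_beta2 = adam_beta2
        self.adam_eps = adam_eps
        self.convergence_tol = convergence_tol
        self.convergence_window = convergence_window
        self.adaptive_mu = adaptive_mu
        self.opi_convention = opi_convention
        self.seed = seed

    def _weights(self) -> LossWeights:
        return LossWeights(self.alpha, self.beta, self.mu, self.gamma, self.sigma)

    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            learning_rate=self.learning_rate,
            fd_step=self.fd_step,
            max_iters=self.max_iters,
            opi_window=self.opi_window,
            opi_threshold=self.opi_threshold,
            mu_cap_ratio=self.mu_cap_ratio,
            adam_beta1=self.adam_beta1,
            adam_beta2=self.adam_beta2,
            adam_eps=self.adam_eps,
            convergence_tol=self.convergence_tol,
            convergence_window=self.convergence_window,
            adaptive_mu=self.adaptive_mu,
            opi_convention=self.opi_convention,
            seed=self.seed,
        )

    def fit(self, X, y=None, seed_xy=None, init_knots=None):
        """Fit the contour to one grayscale image.

        Parameters
        ----------
        X : 2D array or ImageGrid — the image (normalized to [0, 1]).
        y : ignored (estimator API compatibility).
        seed_xy : (cx, cy) — seed point inside the target object; used to
            build the initial circle of knots unless ``init_knots`` given.
        init_knots : (N, 2) array — explicit initial contour, e.g. the
            previous slice's result during volume propagation.
        """
        grid = _as_grid(X)
        config = self._config()
        base_weights = self._weights()
        if base_weights.mu <= 0:
            raise ValueError("mu must be positive for a segmentation run")
        if init_knots is not None:
            knots = ensure_ccw(validate_knots(init_knots))
        else:
            if seed_xy is None:
                raise ValueError("provide seed_xy or init_knots")
            knots = init_circle(seed_xy, self.init_radius, self.n_knots, grid.shape)

        state = OptimizerState(knots=knots, mu_current=base_weights.mu)
        records: list[dict] = []
        j_int_hist: list[float] = []
        j_ext_hist: list[float] = []
        disp_hist: list[float] = []
        best_total = np.inf
        best_knots = knots
        failed = False
        converged = False

        for k in range(config.max_iters):
            w_k = base_weights.replace(mu=state.mu_current)
            try:
                bd: LossBreakdown = total_loss(state.knots, grid, w_k)
                gradient = loss_gradient_fd(state.knots, grid, w_k, config.fd_step)
            except CollapsedContourError:
                failed = True
                break
            if bd.total < best_total:
                best_total, best_knots = bd.total, state.knots.copy()
            j_int_hist.append(bd.j_int)
            j_ext_hist.append(bd.j_ext)

            prev = state.knots
            adam_step(state, gradient, config)

            opi = compute_opi(
                j_int_hist, j_ext_hist, config.opi_window, config.opi_convention
            )
            if config.adaptive_mu and opi is not None:
                state.mu_current = adapt_mu(
                    state.mu_current, bd.j_ext, bd.j_int, opi, config
                )
            records.append(
                {
                    "k": k,
                    "j_psi_s": bd.j_psi_s,
                    "j_psi_ss": bd.j_psi_ss,
                    "j_cv": bd.j_cv,
                    "j_shape": bd.j_shape,
                    "j_int": bd.j_int,
                    "j_ext": bd.j_ext,
                    "total": bd.total,
                    "opi": np.nan if opi is None else opi,
                    "mu": state.mu_current,
                    "area": abs(signed_area(prev)),
                }
            )
            disp_hist.append(
                float(np.mean(np.linalg.norm(state.knots - prev, axis=1)))
            )
            if len(disp_hist) >= config.convergence_window and (
                np.mean(disp_hist[-config.convergence_window :])
                < config.convergence_tol
            ):
                converged = True
                break

        final_knots = best_knots if failed else state.knots
        self.knots_ = final_knots
        self.mask_ = rasterize_polygon(final_knots, grid.shape, check_simple=False)
        self.history_ = pd.DataFrame(records, columns=_HISTORY_COLUMNS)
        self.n_iter_ = len(records)
        self.converged_ = converged
        self.failed_ = failed
        self.mu_ = state.mu_current
        try:
            self.loss_ = total_loss(
                final_knots, grid, base_weights.replace(mu=state.mu_current)
            )
        except CollapsedContourError:
            self.loss_ = None
        self.image_shape_ = grid.shape
        return self

    def predict(self, X=None) -> np.ndarray:
        """Binary mask of the fitted contour on ``X``'s grid (or the
        training grid when ``X`` is None)."""
        if not hasattr(self, "knots_"):
            raise RuntimeError("call fit before predict")
        shape = self.image_shape_ if X is None else _as_grid(X).shape
        return rasterize_polygon(self.knots_, shape, check_simple=False)

    def score(self, X, y) -> float:
        """Dice overlap between the fitted mask and a reference mask ``y``."""
        from .io import dice

        return dice(self.predict(X), np.asarray(y))

    def n_parameters(self) -> int:
        """Trainable parameter count: two coordinates per control knot."""
        return 2 * int(self.n_knots)


class VolumeSegmenter(BaseEstimator):
    """Slice-marching 3D segmentation with transferred initializations.

    Slice 0 is fitted from a circle around ``seed_xy``; slice ``n`` starts
    from slice ``n-1``'s converged knots, which typically converges in far
    fewer iterations.  All :class:`ContourSegmenter` hyperparameters are
    shared across slices unless overridden per slice.

    Attributes: ``knots_`` (list per slice), ``masks_`` (ny, nx, n_slices)
    uint8 volume, ``histories_`` (list of DataFrames), ``n_iters_``,
    ``converged_`` (lists), ``partial_`` (True when a slice collapsed and
    marching stopped early, with earlier slices retained).
    """

    def __init__(
        self,
        alpha: float = 1e-1,
        beta: float = 1e-2,
        mu: float = 1e3,
        gamma: float = 0.0,
        sigma: float = 0.0,
        n_knots: int = 16,
        init_radius: float = 8.0,
        learning_rate: float = 0.5,
        fd_step: float = 1.0,
        max_iters: int = 500,
        opi_window: int = 10,
        opi_threshold: float = 0.8,
        mu_cap_ratio: float = 1e4,
        adam_beta1: float = 0.9,
        adam_beta2: float = 0.999,
        adam_eps: float = 1e-8,
        convergence_tol: float = 0.05,
        convergence_window: int = 10,
        adaptive_mu: bool = True,
        opi_convention: str = "as-printed",
        seed: int = 0,
        per_slice_overrides: dict | None = None,
    ):
        self.alpha = alpha
        self.beta = beta
        self.mu = mu
        self.gamma = gamma
        self.sigma = sigma
        self.n_knots = n_knots
        self.init_radius = init_radius
        self.learning_rate = learning_rate
        self.fd_step = fd_step
        self.max_iters = max_iters
        self.opi_window = opi_window
        self.opi_threshold = opi_threshold
        self.mu_cap_ratio = mu_cap_ratio
        self.adam_beta1 = adam_beta1
        self.adam_beta2 = adam_beta2
        self.adam_eps = adam_eps
        self.convergence_tol = convergence_tol
        self.convergence_window = convergence_window
        self.adaptive_mu = adaptive_mu
        self.opi_convention = opi_convention
        self.seed = seed
        self.per_slice_overrides = per_slice_overrides

    def _slice_estimator(self, index: int) -> ContourSegmenter:
        params = {
            k: v for k, v in self.get_params().items() if k != "per_slice_overrides"
        }
        if self.per_slice_overrides and index in self.per_slice_overrides:
            params.update(self.per_slice_overrides[index])
        return ContourSegmenter(**params)

    @staticmethod
    def _as_stack(X) -> VolumeStack:
        if isinstance(X, VolumeStack):
            return X
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 3:
            raise ValueError(f"volume must be 3D (ny, nx, n_slices), got {arr.shape}")
        return VolumeStack([ImageGrid(arr[..., i]) for i in range(arr.shape[-1])])

    def fit(self, X, y=None, seed_xy=None):
        """Fit every slice of a volume (slices along the last axis)."""
        stack = self._as_stack(X)
        if seed_xy is None:
            raise ValueError("seed_xy (a point inside the object on slice 0) required")
        knots_list: list[np.ndarray] = []
        masks: list[np.ndarray] = []
        histories: list[pd.DataFrame] = []
        n_iters: list[int] = []
        converged: list[bool] = []
        partial = False
        init = None
        for i, grid in enumerate(stack.slices):
            est = self._slice_estimator(i)
            if init is None:
                est.fit(grid, seed_xy=seed_xy)
            else:
                est.fit(grid, init_knots=init)
            if est.failed_:
                partial = True
                break
            knots_list.append(est.knots_)
            masks.append(est.mask_)
            histories.append(est.history_)
            n_iters.append(est.n_iter_)
            converged.append(est.converged_)
            init = est.knots_  # transfer to the next slice
        if not knots_list:
            raise CollapsedContourError("contour collapsed on the first slice")
        self.knots_ = knots_list
        self.masks_ = np.stack(masks, axis=-1)
        self.histories_ = histories
        self.n_iters_ = n_iters
        self.converged_ = converged
        self.partial_ = partial
        self.n_slices_ = len(knots_list)
        return self

    def score(self, X, y) -> float:
        """Mean per-slice Dice against a truth volume (slices last)."""
        from .io import dice

        truth = np.asarray(y)
        scores = [
            dice(self.masks_[..., i], truth[..., i]) for i in range(self.n_slices_)
        ]
        return float(np.mean(scores))


def run_segmentation(grid, init_knots, weights: LossWeights, config: TrainingConfig):
    """Functional wrapper: one descent run from an explicit initial contour.

    Returns ``(knots, mask, history)`` from a fitted
    :class:`ContourSegmenter` configured with ``weights`` and ``config``.
    """
    from dataclasses import asdict

    est = ContourSegmenter(**asdict(weights), **asdict(config))
    est.fit(grid, init_knots=init_knots)
    return est.knots_, est.mask_, est.history_
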