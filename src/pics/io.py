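"""Image/volume ingestion, mask export, Dice evaluation and run configs.

Images (PNG/TIFF, any bit depth) are converted to grayscale when needed and
min-max normalized to [0, 1] at ingest; the region energy is scale
sensitive, so normalization is what makes the shipped coefficient presets
transferable between images.  Volumes are NIfTI files with slices along the
last axis; the affine is preserved on write.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .raster import ImageGrid
from .volume import VolumeStack

__all__ = [
    "dice",
    "load_image",
    "load_volume",
    "save_mask",
    "save_label_volume",
    "PRESETS",
    "RunConfig",
]


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) between two binary masks.

    Two empty masks are identical sets: Dice is defined as 1 (logged as a
    warning since it usually means an upstream failure).
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn("both masks empty: Dice defined as 1", RuntimeWarning, stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def load_image(path) -> ImageGrid:
    """Read a grayscale image file into a normalized :class:`ImageGrid`.

    Color images are collapsed to luminance with a warning; 16-bit input
    normalizes with its own min/max (the maximum pixel maps to 1.0).
    """
    import imageio.v3 as iio

    try:
        arr = np.asarray(iio.imread(path))
    except Exception as err:  # noqa: BLE001 - any decode failure is a format error
        raise ValueError(f"cannot read image file {path!r}: {err}") from err
    if arr.ndim == 3:
        warnings.warn(
            f"{path!r} is not grayscale: converting by luminance", stacklevel=2
        )
        rgb = arr[..., :3].astype(float)
        arr = rgb @ np.array([0.2126, 0.7152, 0.0722])
    return ImageGrid(arr.astype(float), normalize=True)


def load_volume(path) -> VolumeStack:
    """Read a 3D NIfTI file into a :class:`VolumeStack` (slices last)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    stack = VolumeStack([ImageGrid(data[..., i]) for i in range(data.shape[-1])])
    # keep the affine around for round-tripping label volumes
    object.__setattr__(stack, "affine", img.affine)
    return stack


def save_mask(path, mask: np.ndarray) -> None:
    """Write a 2D binary mask as an 8-bit PNG with values {0, 255}."""
    import imageio.v3 as iio

    m = (np.asarray(mask).astype(bool).astype(np.uint8)) * 255
    iio.imwrite(path, m)


def save_label_volume(path, masks: np.ndarray, affine: np.ndarray | None = None) -> None:
    """Write a (ny, nx, n_slices) stack of binary masks as NIfTI labels {0, 1}."""
    import nibabel as nib

    lab = np.asarray(masks).astype(bool).astype(np.uint8)
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(lab, affine), str(path))


# Coefficient presets (alpha, beta, mu, gamma, sigma) for the shipped
# regimes.  tc1..tc4 are the 2D/concavity settings; the acdc-* presets are
# the three cardiac-MRI image classes (normal; indistinct papillary
# muscles, sigma x10; very thin myocardium, gamma x100).
PRESETS: dict[str, dict[str, float]] = {
    "tc1": dict(alpha=1e-1, beta=1e-3, mu=1e4, gamma=0.0, sigma=0.0),
    "tc2a": dict(alpha=1e-1, beta=1e-2, mu=5e4, gamma=0.0, sigma=0.0),
    "tc2b": dict(alpha=5e-1, beta=1e-3, mu=5e4, gamma=0.0, sigma=5e8),
    "tc3a": dict(alpha=5.0, beta=1e-1, mu=1e2, gamma=0.0, sigma=0.0),
    "tc3b": dict(alpha=5e-1, beta=1e-2, mu=1e2, gamma=0.0, sigma=0.0),
    "tc3c": dict(alpha=5e-1, beta=1e-2, mu=1e3, gamma=0.0, sigma=0.0),
    "tc4": dict(alpha=8e-1, beta=1e-3, mu=1e3, gamma=0.0, sigma=0.0),
    "acdc-normal": dict(alpha=1e-1, beta=1e-2, mu=1e4, gamma=1e-5, sigma=1e7),
    "acdc-indistinct": dict(alpha=1e-1, beta=1e-2, mu=1e4, gamma=1e-5, sigma=1e8),
    "acdc-thin": dict(alpha=1e-1, beta=1e-2, mu=1e4, gamma=1e-3, sigma=1e7),
}


@dataclass
class RunConfig:
    """Everything one segmentation run needs, serializable to YAML."""

    # loss coefficients
    alpha: float = 1e-1
    beta: float = 1e-2
    mu: float = 1e3
    gamma: float = 0.0
    sigma: float = 0.0
    # initialization
    seed_xy: tuple[float, float] = (64.0, 64.0)
    init_radius: float = 8.0
    n_knots: int = 16
    # training
    learning_rate: float = 0.5
    fd_step: float = 1.0
    max_iters: int = 500
    opi_window: int = 10
    opi_threshold: float = 0.8
    mu_cap_ratio: float = 1e4
    convergence_tol: float = 0.05
    convergence_window: int = 10
    adaptive_mu: bool = True
    opi_convention: str = "as-printed"
    seed: int = 0
    # paths (optional; None when driven programmatically)
    image: str | None = None
    volume: str | None = None
    out: str | None = None
    log: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["seed_xy"] = list(self.seed_xy)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "seed_xy" in d:
            d["seed_xy"] = tuple(float(x) for x in d["seed_xy"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def estimator_params(self) -> dict:
        """Parameters for :class:`pics.estimators.ContourSegmenter`."""
        skip = {"seed_xy", "image", "volume", "out", "log"}
        return {k: v for k, v in asdict(self).items() if k not in skip}
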