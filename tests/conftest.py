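import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


def random_contour(rng, n_knots=8, center=(16.0, 16.0), r_min=4.0, r_max=10.0):
    """Random simple closed contour (star-shaped knot polygon).

    Angular gaps are bounded so every edge stays in its angular wedge,
    guaranteeing a simple polygon for any radii.
    """
    gaps = rng.uniform(0.4, 1.0, n_knots)
    ang = 2 * np.pi * np.cumsum(gaps) / gaps.sum()
    rad = rng.uniform(r_min, r_max, n_knots)
    cx, cy = center
    return np.stack([cx + rad * np.cos(ang), cy + rad * np.sin(ang)], axis=1)
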