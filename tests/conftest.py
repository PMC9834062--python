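import math

import numpy as np
import pytest

import smlmfit as sf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cloud2d(rng):
    """Isotropic 2D Gaussian cloud around (5, -3) with per-point sigmas."""
    n = 40
    sig = rng.uniform(3.0, 12.0, size=(n, 2))
    coords = np.array([5.0, -3.0]) + rng.normal(0.0, sig)
    return sf.LocalizationSet(coords, sig)


@pytest.fixture
def site3d(rng):
    """A 3D site with a loose localization cloud (no structure)."""
    n = 60
    sig = rng.uniform(4.0, 15.0, size=(n, 3))
    coords = rng.uniform(-100.0, 100.0, size=(n, 3))
    locs = sf.LocalizationSet(coords, sig)
    return sf.Site(locs, side_length=300.0, center=np.zeros(3))


def make_site(coords, precisions, side=300.0, channel=None):
    locs = sf.LocalizationSet(coords, precisions, channel=channel)
    return sf.Site(locs, side_length=side, center=np.zeros(locs.ndim))


@pytest.fixture
def single_point_model():
    """Discrete model with a single point at the origin (3D)."""
    from smlmfit.models import GeometricModel, _model_points

    def _eval(v, spacing):
        return _model_points(np.zeros((1, 3)))

    return GeometricModel("point", "discrete-points", 3, (), _eval)
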