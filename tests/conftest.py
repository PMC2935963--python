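import numpy as np
import pytest

from pqctshape import AnalysisConfig, ImageGeometry, PhantomSpec, rasterize


@pytest.fixture(scope="session")
def annulus():
    """Default circular-annulus phantom (R=13, r=9, v=0.5) with truth."""
    image, truth = rasterize(PhantomSpec())
    return image, truth


@pytest.fixture(scope="session")
def annulus_analysis(annulus):
    from pqctshape import analyze_image

    image, truth = annulus
    return analyze_image(image), truth


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def random_ring_mask(rng, size=28):
    """Small random ring-topology mask for oracle comparisons.

    A blobby annulus: random center, radii and angular modulation, rasterized
    on a size x size grid; guaranteed one component, one hole, off-border.
    """
    R = rng.uniform(size * 0.28, size * 0.38)
    r = rng.uniform(size * 0.12, R - size * 0.12)
    amp = rng.uniform(0.0, 0.08)
    phase = rng.uniform(0, 2 * np.pi)
    c = size / 2.0 + rng.uniform(-1, 1, size=2)
    ii, jj = np.mgrid[0:size, 0:size]
    x = jj + 0.5 - c[1]
    y = ii + 0.5 - c[0]
    theta = np.arctan2(y, x)
    rho = np.hypot(x, y)
    outer = R * (1 + amp * np.cos(3 * theta + phase))
    inner = r * (1 + amp * np.cos(2 * theta - phase))
    return (rho <= outer) & (rho > inner)
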