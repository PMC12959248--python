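import numpy as np
import pytest

from melmorph.synthetic import SyntheticCohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (n=2000, default seed) and its truth."""
    return generate_cohort(SyntheticCohortSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260304)


def random_convex_hull(rng, n_points=30, scale=10.0):
    """Vertices (CCW) of the convex hull of a random point cloud."""
    from scipy.spatial import ConvexHull

    pts = rng.normal(size=(n_points, 2)) * scale
    hull = ConvexHull(pts)
    return pts[hull.vertices]
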