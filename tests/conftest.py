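import numpy as np
import pytest

from lqli.geometry import FrontAnnotation, RectangleROI, build_roi
from lqli.profiling import DensityProfile


@pytest.fixture
def horizontal_front():
    """Front along y=0 traveling +x with tumor below (y > 0, image y-down)."""
    return FrontAnnotation(
        points=np.array([[-5000.0, 0.0], [5000.0, 0.0]]), tumor_side="right"
    )


@pytest.fixture
def default_roi(horizontal_front) -> RectangleROI:
    """Rectangle anchored at (0, 0) with the tumor toward +y."""
    return build_roi(horizontal_front, arc_position=5000.0)


def make_profile(density, length=4000.0) -> DensityProfile:
    density = np.asarray(density, dtype=float)
    edges = np.linspace(0.0, length, len(density) + 1)
    return DensityProfile(bin_edges=edges, density=density)


@pytest.fixture
def profile_factory():
    return make_profile
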