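import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from antagonav.plume_field import FieldSlice2D

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_slice(values, x, y, radius, times=None, source_xy=(0.0, 0.0)):
    """Build a FieldSlice2D directly from dense values (n_times, nx, ny)."""
    times = times if times is not None else np.array([0.0])
    xs, ys = np.meshgrid(x, y, indexing="ij")
    mask = xs**2 + ys**2 <= radius**2
    return FieldSlice2D(
        plane_z=-0.5, times=np.asarray(times, float), x=np.asarray(x, float),
        y=np.asarray(y, float), values=np.asarray(values, float), mask=mask,
        radius=radius, source_xy=source_xy,
    )


@pytest.fixture
def linear_slice():
    """C = 1 + 0.1 x (per mm) on a 21x21 grid of radius 10."""
    x = np.arange(-10.0, 10.5, 1.0)
    vals = (1.0 + 0.1 * x)[None, :, None] * np.ones((1, x.size, x.size))
    return make_slice(vals, x, x, radius=10.0)


@pytest.fixture(scope="session")
def standard_slice():
    """Coarse standard-arena slice shared across cohort tests."""
    from antagonav.arena import standard_field_slice

    return standard_field_slice()


@pytest.fixture(scope="session")
def standard_params(standard_slice):
    from antagonav.arena import field_scaled_params

    return field_scaled_params(standard_slice)
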