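import numpy as np
import pytest

from cardiowarp import (
    PhantomSpec,
    build_directions,
    es_configuration,
    make_phantom_mesh,
    render_image_series,
)


@pytest.fixture(scope="session")
def small_spec():
    """Coarse, fast phantom used throughout the unit tests."""
    return PhantomSpec(
        noise_sd=0.0,
        n_frames=6,
        es_frame=3,
        grid_shape=(48, 48, 12),
        grid_spacing=(3.0, 3.0, 8.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_mesh_ed(small_spec):
    return make_phantom_mesh(small_spec)


@pytest.fixture(scope="session")
def small_mesh_es(small_spec, small_mesh_ed):
    return es_configuration(small_spec, small_mesh_ed)


@pytest.fixture(scope="session")
def small_directions(small_mesh_es):
    return build_directions(small_mesh_es)


@pytest.fixture(scope="session")
def small_series(small_spec):
    return render_image_series(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
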