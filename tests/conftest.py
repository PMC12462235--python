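import numpy as np
import pytest

import cuticlemap as cm


@pytest.fixture(scope="session")
def small_slab():
    spec = cm.PhantomSpec(kind="slab", grid_shape=(24, 32, 32), wall_thickness=5)
    return spec, *cm.make_phantom(spec)


@pytest.fixture(scope="session")
def small_shell():
    spec = cm.PhantomSpec(
        kind="spherical_shell", grid_shape=(32, 32, 32), outer_radius=12, wall_thickness=3
    )
    return spec, *cm.make_phantom(spec)


@pytest.fixture(scope="session")
def small_capsule():
    spec = cm.PhantomSpec(
        kind="capsule_pouch",
        grid_shape=(40, 36, 36),
        outer_radius=14,
        wall_thickness=2,
        ventral_dorsal_factor=2.0,
        pouch_depth_fraction=0.25,
    )
    return spec, *cm.make_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
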