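import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lumivox as lv

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sphere64():
    """Centered solid sphere, radius 20 voxels, in a 64^3 unit-spacing grid."""
    return lv.make_phantom(
        lv.PhantomSpec(kind="solid_sphere", radius=20.0), dims=(64, 64, 64)
    )


@pytest.fixture(scope="session")
def opaque_tf():
    return lv.make_test_tf("opaque_surface")


@pytest.fixture(scope="session")
def sphere_field72(sphere64, opaque_tf):
    """Ambient field of the solid sphere under the full 72-light rig."""
    vol, _ = sphere64
    cfg = lv.PrecomputeConfig(n_lights=72, rays_per_light=1024, seed=1)
    return lv.precompute_field(vol, opaque_tf, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def surface_mask(inside: np.ndarray) -> np.ndarray:
    """Material voxels with at least one non-material 6-neighbor."""
    surf = np.zeros_like(inside)
    for ax in range(3):
        for sh in (1, -1):
            surf |= inside & ~np.roll(inside, sh, axis=ax)
    return surf
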