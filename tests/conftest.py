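import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from parascint.phantom import (  # noqa: E402
    Ellipsoid,
    PhantomSpec,
    build_activity_volume,
)


@pytest.fixture(scope="session")
def unit_sphere_spec() -> PhantomSpec:
    """Small isotropic phantom: a 5 mm-radius unit-uptake sphere on a zero
    background (thyroid lobes tucked into a corner, out of the way)."""
    return PhantomSpec(
        grid_shape=(40, 40, 40),
        voxel_spacing=(1.0, 1.0, 1.0),
        adenoma=Ellipsoid((20.0, 20.0, 20.0), (5.0, 5.0, 5.0)),
        thyroid_lobes=(
            Ellipsoid((4.0, 4.0, 4.0), (2.0, 2.0, 2.0), side="right"),
            Ellipsoid((35.0, 4.0, 4.0), (2.0, 2.0, 2.0), side="left"),
        ),
        compartment_uptake_early={"adenoma": 1.0, "thyroid": 0.5, "background": 0.0},
        effective_half_life={"adenoma": np.inf, "thyroid": np.inf, "background": np.inf},
        psf_sigma=0.0,
        count_scale=1000.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def neck_phantom_volumes():
    """Default neck phantom, noise-free early and delayed volumes."""
    spec = PhantomSpec()
    return (
        build_activity_volume(spec, "early"),
        build_activity_volume(spec, "delayed"),
        spec,
    )
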