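"""Shared fixtures: small, fast phantoms and beam models.

The `mini` phantom (48^3 voxels, 8 mm tumor, 6 mm motion) keeps unit tests
fast; the full-size default phantom is reserved for the acceptance suite.
"""

import numpy as np
import pytest

from spotlab.beam import large_beam_model, small_beam_model
from spotlab.grid import DoseGrid
from spotlab.phantom import PhantomConfig, generate_phantom

MINI = dict(shape=(48, 48, 48), gtv_radius_mm=8.0, amplitude_mm=6.0,
            jitter_mm=0.0)


@pytest.fixture(scope="session")
def mini_phantom():
    return generate_phantom(PhantomConfig(**MINI), seed=3)


@pytest.fixture(scope="session")
def static_phantom():
    return generate_phantom(PhantomConfig(**{**MINI, "amplitude_mm": 0.0}),
                            seed=3)


@pytest.fixture(scope="session")
def small_beam():
    return small_beam_model()


@pytest.fixture(scope="session")
def large_beam():
    return large_beam_model()


@pytest.fixture(scope="session")
def water_grid():
    """Homogeneous water block; beam along +y enters at the first y-plane."""
    return DoseGrid(np.ones((60, 80, 60), dtype=np.float32), (3.0, 3.0, 3.0),
                    (-88.5, -10.0, -88.5))


@pytest.fixture(scope="session")
def mini_plan(mini_phantom, small_beam):
    """A small optimized + normalized single-field plan for reuse."""
    from spotlab.beam import plan_dose
    from spotlab.optimize import OptimizationSettings, robust_optimize
    from spotlab.planning import normalize_d99, place_spots

    plan = place_spots(mini_phantom, small_beam, ((0.0, 1.0, 0.0),))
    res = robust_optimize(plan, small_beam, mini_phantom,
                          OptimizationSettings(iterations=300))
    dose = plan_dose(res.plan, small_beam, mini_phantom.reference_grid)
    plan_n, scale = normalize_d99(res.plan, dose, mini_phantom.masks["CTV"])
    return plan_n, dose.like(dose.values * scale)
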