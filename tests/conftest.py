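import numpy as np
import pytest

from oslet.phantom import VoxelPhantom, build_phantom, place_osld_roi
from oslet.planning import make_reference_plan
from oslet.transport import StoppingModel


def water_box(shape=(40, 60, 40), spacing=2.0, density=1.0):
    """Uniform box of the given density surrounded by nothing (the whole grid
    is the medium) -- a plain slab phantom for transport checks."""
    dens = np.full(shape, density, dtype=np.float32)
    masks = {"body": np.ones(shape, dtype=bool)}
    sp = np.full(3, float(spacing))
    return VoxelPhantom(spacing=sp, origin=sp / 2, density=dens, masks=masks)


@pytest.fixture(scope="session")
def phantom():
    """The default 2 mm head-and-neck phantom with the seven-detector ROI."""
    return place_osld_roi(build_phantom())


@pytest.fixture(scope="session")
def reference_plan(phantom):
    """Three-field reference plan optimized on the nominal phantom."""
    return make_reference_plan(phantom)


@pytest.fixture(scope="session")
def prepared_suite(phantom, reference_plan):
    """Reference plan + daily geometries + daily DAPT plans, shared across
    suite-level tests (all deterministic, seed-independent)."""
    from oslet.phantom import Scenario, apply_scenario
    from oslet.planning import make_daily_plan
    from oslet.workbench import FRACTION_TABLE, PreparedSuite

    daily = {fx: apply_scenario(phantom, Scenario(kind=kind))
             for fx, kind, _, _ in FRACTION_TABLE}
    daily_plans = {fx: make_daily_plan(reference_plan, daily[fx])
                   for fx, _, modes, meas in FRACTION_TABLE if "DAPT" in meas}
    return PreparedSuite(phantom=phantom, plan=reference_plan, daily=daily,
                         daily_plans=daily_plans)


@pytest.fixture()
def model():
    return StoppingModel()


@pytest.fixture()
def quiet_model():
    """Deterministic transport: no straggling, no lateral scattering."""
    return StoppingModel(straggling_fraction=0.0, scattering=False)
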