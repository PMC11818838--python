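import numpy as np
import pytest

from kneevar.contact import CartilageLayer, ContactPairSpec
from kneevar.knee_model import LoadProtocol, run_branch
from kneevar.materials import YeohParams
from kneevar.sampling import MaterialRanges
from kneevar.synthetic_knee import default_model, nominal_curves


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250929)


@pytest.fixture(scope="session")
def table_hull():
    """Convex hull of all published Yeoh ranges, as (lo, hi) per constant."""
    r = MaterialRanges()
    bounds = np.minimum(r.healthy.bounds(), r.oa.bounds()), np.maximum(
        r.healthy.bounds(), r.oa.bounds()
    )
    lo = np.minimum(bounds[0][:, 0], bounds[1][:, 0])
    hi = np.maximum(bounds[0][:, 1], bounds[1][:, 1])
    return np.column_stack([lo, hi])


def pair_spec(fem: YeohParams, tib: YeohParams) -> ContactPairSpec:
    return ContactPairSpec(
        sphere_radius=40.0,
        femoral=CartilageLayer(2.3, fem),
        tibial=CartilageLayer(2.1, tib),
    )


@pytest.fixture(scope="session")
def mid_healthy_spec():
    return pair_spec(YeohParams(1.4, 3.65), YeohParams(2.0, 4.5))


@pytest.fixture(scope="session")
def nominal_model():
    return default_model()


@pytest.fixture(scope="session")
def healthy_curves():
    return nominal_curves("healthy")


@pytest.fixture(scope="session")
def oa_curves():
    return nominal_curves("oa")


@pytest.fixture(scope="session")
def nominal_branches(nominal_model, healthy_curves):
    """Extension and flexion branches of the nominal model, healthy tissue."""
    ext = run_branch(nominal_model, healthy_curves, LoadProtocol("extension"))
    flex = run_branch(nominal_model, healthy_curves, LoadProtocol("flexion"))
    return ext, flex


@pytest.fixture(scope="session")
def nominal_branches_oa(nominal_model, oa_curves):
    ext = run_branch(nominal_model, oa_curves, LoadProtocol("extension"))
    flex = run_branch(nominal_model, oa_curves, LoadProtocol("flexion"))
    return ext, flex
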