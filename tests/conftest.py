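import numpy as np
import pytest

from pollendep import (
    FieldParams,
    LeafGeometry,
    PilotScan,
    generate_field,
    make_fixtures,
)


@pytest.fixture(scope="session")
def geometry():
    return LeafGeometry()


@pytest.fixture(scope="session")
def default_field():
    return generate_field(FieldParams(seed=11))


@pytest.fixture(scope="session")
def default_pilot(default_field):
    return PilotScan.from_field(default_field)


@pytest.fixture(scope="session")
def two_level_field():
    """Noise-free field: 1000 pollen/cm^2 in the midrib band, 100 elsewhere."""
    params = FieldParams(
        background_gm=100.0, background_gsd=1.0,
        midrib_multiplier=10.0, vein_multiplier=1.0, edge_multiplier=1.0,
        seed=0,
    )
    return generate_field(params)


@pytest.fixture(scope="session")
def fixture_bundle():
    return make_fixtures(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
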