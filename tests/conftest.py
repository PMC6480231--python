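import numpy as np
import pytest

from tunnelear import (
    EarParameters,
    TransitGeometry,
    generate_exterior_trace,
    interior_pressure,
    reference_tables,
)


@pytest.fixture(scope="session")
def reference():
    """Packaged published coefficients and thresholds: (fits, threshold_sets)."""
    return reference_tables()


@pytest.fixture
def geometry():
    return TransitGeometry(tunnel_length=350.0, train_length=79.77,
                           speed=250.0, point_id="MP-1")


@pytest.fixture
def ear_params():
    return EarParameters()


@pytest.fixture
def interior_trace(geometry):
    """One calibrated interior trace (250 km/h, MP-1, omega = 4 s)."""
    return interior_pressure(generate_exterior_trace(geometry, seed=7), 4.0)
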