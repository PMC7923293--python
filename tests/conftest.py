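import numpy as np
import pytest

from oraflux.biopharm import rivaroxaban_properties
from oraflux.pk_disposition import (ConcentrationTimeProfile,
                                    DispositionParams, FirstOrderOral,
                                    simulate_disposition)

# fitted two-compartment disposition of the 10 mg oral solution:
# CL 9.43 L/h, Vc 0.47 L/kg, k12 0.04 /h, k21 0.21 /h, V2 0.09 L/kg
TABLE3 = dict(n_compartments=2, clearance=9.43, vc_per_kg=0.47,
              k12=0.04, k21=0.21, v2_per_kg=0.09)


@pytest.fixture(scope="session")
def disposition():
    return DispositionParams(body_mass=70.0, **TABLE3)


@pytest.fixture(scope="session")
def drug():
    return rivaroxaban_properties()


@pytest.fixture(scope="session")
def grid_24h():
    return np.arange(0.25, 24.01, 0.25)


@pytest.fixture(scope="session")
def solution_profile(disposition, grid_24h):
    """Noise-free 10 mg oral-solution profile (ka = 2 /h)."""
    return simulate_disposition(disposition, FirstOrderOral(10.0, 2.0),
                                grid_24h)
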