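import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from agederm.em_solver import PlaneWaveExposure, analyze
from agederm.synthetic_data import default_fixture
from agederm.tissue_model import ComplexPermittivity, TissueLayer, build_adult_stack


@pytest.fixture(scope="session", params=[26e9, 60e9], ids=["26GHz", "60GHz"])
def frequency(request):
    return request.param


@pytest.fixture(scope="session")
def adult_stack(frequency):
    return build_adult_stack(frequency)


@pytest.fixture(scope="session")
def adult_em(frequency, adult_stack):
    return analyze(adult_stack, PlaneWaveExposure(frequency, 10.0))


@pytest.fixture(scope="session")
def age_tables():
    return default_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def layers_from_eps(eps_list, thicknesses, frequency, density=1000.0):
    """Build bare TissueLayers from complex permittivities (test helper)."""
    return [
        TissueLayer(
            f"L{i}",
            thicknesses[i],
            {frequency: ComplexPermittivity(e.real, -e.imag)},
            thermal_conductivity=0.4,
            density=density,
        )
        for i, e in enumerate(eps_list)
    ]
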