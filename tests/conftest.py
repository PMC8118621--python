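import pytest

from coastvuln.exposure import run_scenarios
from coastvuln.synth import RegionSpec, generate_region


@pytest.fixture(scope="session")
def region():
    """One mid-sized synthetic region shared across the suite."""
    return generate_region(RegionSpec(seed=7, coast_length_km=300.0))


@pytest.fixture(scope="session")
def region_exposure(region):
    return run_scenarios(region["points"], region["habitat_layers"])
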