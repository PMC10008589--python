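import pytest
from hypothesis import HealthCheck, settings

from dartvadar.construct_assembler import load_components
from dartvadar.fixture_sim import SimSpec, make_trigger
from dartvadar.sensor_designer import design_sensor
from dartvadar.site_finder import scan_cca

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def components():
    return load_components()


@pytest.fixture(scope="session")
def trigger():
    """Default synthetic trigger: 500 nt, 60-nt 5'UTR, 300-nt CDS, one CCA at +60."""
    return make_trigger(SimSpec(seed=1))


@pytest.fixture(scope="session")
def design75(trigger):
    site = scan_cca(trigger)[0]
    design = design_sensor(trigger, site)
    assert design.length == 75
    return design
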