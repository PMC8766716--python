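import pytest
from hypothesis import HealthCheck, settings

from ctdnakit.core_model import MarkerSpec
from ctdnakit.synthetic_data import SimConfig

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def kras_marker():
    """KRAS c.35G>A (p.Gly12Asp), the transition marker used throughout."""
    return MarkerSpec.from_hgvs("KRAS_c35GA", "KRAS", "c.35G>A", "p.Gly12Asp")


@pytest.fixture
def transversion_marker():
    return MarkerSpec.from_hgvs("KRAS_c34GT", "KRAS", "c.34G>T", "p.Gly12Cys")


@pytest.fixture
def base_cfg():
    return SimConfig(seed=7, coverage_target=150_000, input_mass_ng=20.0)
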