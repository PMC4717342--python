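import pytest
from hypothesis import HealthCheck, settings

from cotrans import StrainParams

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def field_params() -> StrainParams:
    """Transmission efficiencies measured in singly infected lines (96% / 94.3%)."""
    return StrainParams(0.96, 0.943, "LbFV1", "LbFV2")
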