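import pytest
from hypothesis import HealthCheck, settings

from cervdisc import OsmoticConstants, load_reference_table

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def refs():
    """Packaged per-level disc reference table with default osmotic settings."""
    return load_reference_table()


@pytest.fixture(scope="session")
def ref_c2c3(refs):
    return refs[0]


@pytest.fixture(scope="session")
def constants():
    return OsmoticConstants()
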