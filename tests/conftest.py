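import pytest
from hypothesis import HealthCheck, settings

from srna_signature.sequences import Region
from srna_signature.simulate import TRIGGER_MIDGFP, default_reference

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ref():
    return default_reference()


@pytest.fixture(scope="session")
def trigger() -> Region:
    return TRIGGER_MIDGFP
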