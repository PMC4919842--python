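import pytest
from hypothesis import HealthCheck, settings

from semschema.demo import build_demo_schema
from semschema.registry import load_registry
from semschema.terminology import packaged_lexicon

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def lexicon():
    return packaged_lexicon()


@pytest.fixture()
def demo_schema():
    return build_demo_schema()
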