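import hypothesis
import pytest

from zonalspi.simulate import SyntheticConfig, generate, make_pillar_config

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset (71 regions, 22 indicators)."""
    return generate(SyntheticConfig(seed=20240817))


@pytest.fixture(scope="session")
def pillar_config():
    return make_pillar_config()
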