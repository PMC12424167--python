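import pytest

from condsurf import GeneratorConfig


@pytest.fixture(scope="session")
def gen_config() -> GeneratorConfig:
    """Default generator at the study's operating point, fixed seed."""
    return GeneratorConfig(seed=1)
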