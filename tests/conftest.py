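import pytest
from hypothesis import settings

from fibersavings import default_base_case

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def adult_cfg():
    """All four strata present, adult scope (the published base case)."""
    cfg = default_base_case("all")
    cfg.population_scope = "adult"
    return cfg


@pytest.fixture
def pediatric_cfg():
    return default_base_case("pediatric")
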