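import hypothesis
import pytest

import igtcea as ig

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def base_params() -> ig.ParameterSet:
    return ig.load_parameters()


@pytest.fixture(scope="session")
def life_table() -> ig.LifeTable:
    """Default synthetic Gompertz-Makeham life table, ages 0-110."""
    return ig.generate_life_table()


@pytest.fixture(scope="session")
def immortal_table() -> ig.LifeTable:
    """All-zero mortality, for hand-checkable engine arithmetic."""
    return ig.generate_life_table(
        ig.GompertzMakehamParams(makeham=0.0, gompertz_a=0.0, gompertz_b=0.1)
    )


@pytest.fixture(scope="session")
def ctx50(base_params, life_table) -> ig.ModelContext:
    return ig.ModelContext(params=base_params, life_table=life_table, horizon=50)
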