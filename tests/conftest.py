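import pytest
from hypothesis import HealthCheck, settings

from formulanet.formula import ElementRules
from formulanet.network import ReactionTable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reactions() -> ReactionTable:
    return ReactionTable.default()


@pytest.fixture(scope="session")
def rules() -> ElementRules:
    return ElementRules()


@pytest.fixture(scope="session")
def small_study(reactions, rules):
    """A compact synthetic acquisition shared by pipeline-level tests."""
    from formulanet.synth import make_study

    return make_study(
        rng_seed=11,
        n_universe=400,
        n_truth=40,
        n_noise=120,
        n_contaminants=20,
        reactions=reactions,
        rules=rules,
    )
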