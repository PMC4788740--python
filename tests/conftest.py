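import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from retrievalqc import BetaPrior, ConfusionTable, StratifiedSample

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def ecig_design() -> StratifiedSample:
    """The e-cigarette stratified coding sample: 4373 of 82,205 retrieved,
    6305 of 3,872,370 unretrieved."""
    return StratifiedSample(
        retrieved_sampled=4373,
        unretrieved_sampled=6305,
        retrieved_population=82_205,
        unretrieved_population=3_872_370,
    )


@pytest.fixture
def adjusted_table() -> ConfusionTable:
    """The sampling-fraction-adjusted filter-vs-coder table."""
    return ConfusionTable(a=128, b=6, c=20, d=6285)


@pytest.fixture
def unarchived_priors() -> dict[str, BetaPrior]:
    """Elicited beta priors matching the unarchived-model prior columns."""
    from retrievalqc import elicit_beta

    return {
        "pi": elicit_beta(0.010, (1e-6, 0.031)),
        "S": elicit_beta(0.667, (0.340, 0.954)),
        "C": elicit_beta(0.733, (0.474, 0.962)),
    }


@pytest.fixture
def latent_priors() -> dict[str, BetaPrior]:
    """Elicited beta priors matching the latent-class prior columns."""
    from retrievalqc import elicit_beta

    return {
        "pi": elicit_beta(0.019, (1e-6, 0.031)),
        "S1": elicit_beta(0.667, (0.340, 0.954)),
        "C1": elicit_beta(0.733, (0.474, 0.962)),
        "S2": elicit_beta(0.733, (0.474, 0.962)),
        "C2": elicit_beta(0.800, (0.616, 0.975)),
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
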