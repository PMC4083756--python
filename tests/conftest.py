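import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pathmm import (
    AminoAcidDistribution,
    BackgroundComposition,
    FixtureConfig,
    ModelSource,
    ProfileHMM,
    simulate,
)

settings.register_profile(
    "pathmm",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("pathmm")


def random_distribution(rng: np.random.Generator, alpha: float = 0.5) -> AminoAcidDistribution:
    p = np.maximum(rng.dirichlet(np.full(20, alpha)), 1e-9)
    return AminoAcidDistribution(p / p.sum())


def make_profile(
    rng: np.random.Generator,
    model_id: str = "M",
    length: int = 10,
    source: ModelSource = ModelSource.AB_INITIO,
    residue_map=None,
) -> ProfileHMM:
    emissions = tuple(random_distribution(rng) for _ in range(length))
    if residue_map is None:
        residue_map = {i: i for i in range(1, length + 1)}
    return ProfileHMM(model_id, source, length, emissions, residue_map)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def background():
    return BackgroundComposition.uniform()


@pytest.fixture(scope="session")
def planted_fixture():
    """Default study conditions: strong planted disease-specific signal."""
    return simulate(FixtureConfig(seed=7))


@pytest.fixture(scope="session")
def balanced_fixture():
    """Uniform variant placement: balanced weights, conservation-only signal."""
    return simulate(FixtureConfig(seed=7, weight_bias=0.0))
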