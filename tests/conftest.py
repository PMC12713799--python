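import numpy as np
import pytest

from dreamcue import synthgen
from dreamcue.semantics import HashedTokenEmbedder
from dreamcue.session import Condition, CueObject, SessionConfig


@pytest.fixture
def default_config() -> SessionConfig:
    return SessionConfig(
        participant_id="P0001",
        condition=Condition.HYPNAGOGIA,
        cue_object=CueObject.TREE,
        latency_min_s=600,
        latency_max_s=900,
        rng_seed=7,
    )


@pytest.fixture
def embedder() -> HashedTokenEmbedder:
    return HashedTokenEmbedder()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared across tests (regenerating it is
    cheap but reuse keeps the suite fast)."""
    return synthgen.generate_cohort(synthgen.CohortParams(n_recruited=60, seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    return synthgen.generate_cohort(synthgen.CohortParams(seed=42))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
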