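import numpy as np
import pytest

from semrsa import synthetic
from semrsa.semantic import RDM, EmbeddingTable, FeatureNorms


@pytest.fixture(scope="session")
def small_norms() -> FeatureNorms:
    return synthetic.generate_feature_norms(
        n_concepts=12, n_features=48, n_categories=4, seed=1)


@pytest.fixture(scope="session")
def small_embeddings(small_norms) -> EmbeddingTable:
    vocab = {w for f in small_norms.features for w in f.split()}
    return synthetic.generate_embeddings(vocab, d=50, seed=1)


@pytest.fixture(scope="session")
def model_rdm(small_norms, small_embeddings) -> RDM:
    return synthetic.make_model_rdm_from_norms(small_norms, small_embeddings)


@pytest.fixture(scope="session")
def small_cohort(model_rdm):
    spec = synthetic.CohortSpec(effect_rdm=model_rdm, n_participants=3,
                                snr=5.0, seed=3)
    return synthetic.generate_cohort(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
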