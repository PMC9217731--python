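import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cafedsim.param_model import ParamVector
from cafedsim.synthetic_data import CorpusSpec, gen_corpus, gen_embedding_table
from cafedsim.text_pipeline import bag_of_words, minmax_normalize


@pytest.fixture(scope="session")
def small_corpus():
    """300-user strongly separable corpus + its embedding table."""
    spec = CorpusSpec(n_users=300, vocab_size=300, signal_tokens=20,
                      signal_strength=2.5, seed=7)
    records, log_odds = gen_corpus(spec)
    table = gen_embedding_table(spec.vocab_size, dim=16, seed=8)
    return spec, records, log_odds, table


@pytest.fixture(scope="session")
def logistic_data():
    """Linearly separable dense features for the logistic stand-in."""
    rng = np.random.default_rng(11)
    n, dim = 400, 8
    w_true = rng.normal(size=dim)
    X = rng.normal(size=(n, dim))
    y = (X @ w_true + 0.3 * rng.normal(size=n) > 0).astype(int)
    return X, y


@pytest.fixture(scope="session")
def bow_dataset(small_corpus):
    """Normalized bag-of-words features from the small corpus."""
    spec, records, _, table = small_corpus
    X = bag_of_words(records, table.vocabulary)
    X, _ = minmax_normalize(X, "fit")
    y = np.array([r.label for r in records])
    return X, y


def make_pv(*arrays):
    return ParamVector.from_named(
        (f"p{i}", np.asarray(a, dtype=float)) for i, a in enumerate(arrays)
    )
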