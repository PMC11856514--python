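"""Shared fixtures.

The learning-sanity training run (500 synthetic sentences, 15 epochs on
CPU) is expensive, so it is computed once per session and shared between
the training-behaviour tests and the acceptance test that asserts its
validation F1.
"""

from __future__ import annotations

import numpy as np
import pytest

from gcaner import RunConfig, train
from gcaner.synthetic import SynthSpec, generate
from gcaner.tagging import EntitySpan

# The worked example sentence: two entities, "eye pain" and "swelling".
EXAMPLE_TOKENS = ["眼", "睛", "痛", "肿", "胀", "是", "什", "么", "原", "因"]
EXAMPLE_SPANS = [EntitySpan(0, 3), EntitySpan(3, 5)]
EXAMPLE_TAGS = ["B", "I", "E", "B", "E", "O", "O", "O", "O", "O"]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def sanity_spec():
    """Study conditions of the learning-sanity run: 500 sentences, three
    entity categories, two entities per sentence in expectation, seed 13."""
    return SynthSpec(n_sentences=500, categories=("dis", "sym", "dru"),
                     entity_density=2.0, seed=13)


@pytest.fixture(scope="session")
def sanity_corpus(sanity_spec):
    return generate(sanity_spec)


def desk_config(**overrides) -> RunConfig:
    """Desk-scale training configuration: model dim 64, 15 epochs, the
    standard adaptive-moment learning rate for from-scratch training."""
    base = dict(epochs=15, batch_size=16, learning_rate=1e-3, hidden_dim=32,
                embedding_dim=32, model_dim=64, seed=13)
    base.update(overrides)
    return RunConfig(**base)


@pytest.fixture(scope="session")
def sanity_run(sanity_corpus):
    """The full GCA model trained under the learning-sanity protocol."""
    import io
    log = io.StringIO()
    result = train(desk_config(), sanity_corpus, log=log)
    result.log_text = log.getvalue()
    return result
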