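"""Shared fixtures: a small fixture corpus and an overfit seq2seq model.

The trained model is expensive (200 epochs), so it is built once per
session and reused by the model, generator and acceptance tests.
"""

from __future__ import annotations

import pytest

from latentmol import (FixtureSpec, ModelConfig, Seq2SeqModel,
                       build_alphabet, random_corpus, smiles_to_selfies)
from latentmol.selfies_coder import encode_sequence, vectorize

CORPUS_SIZE = 100


@pytest.fixture(scope="session")
def small_corpus():
    """100 short fixture molecules as canonical generic SMILES."""
    records = random_corpus(FixtureSpec(
        n_molecules=CORPUS_SIZE, length_range=(8, 16), rng_seed=5))
    return [r.smiles_generic for r in records]


@pytest.fixture(scope="session")
def corpus_selfies(small_corpus):
    """Canonical SELFIES of the corpus (the model's training strings)."""
    return [smiles_to_selfies(s) for s in small_corpus]


@pytest.fixture(scope="session")
def alphabet(corpus_selfies):
    return build_alphabet(corpus_selfies)


@pytest.fixture(scope="session")
def onehot_corpus(corpus_selfies, alphabet):
    return [vectorize(encode_sequence(s, alphabet), alphabet)
            for s in corpus_selfies]


@pytest.fixture(scope="session")
def overfit_model(alphabet, onehot_corpus):
    """Model trained to reconstruction on the fixture corpus (200 epochs)."""
    model = Seq2SeqModel(alphabet, ModelConfig(rng_seed=0))
    model.fit(onehot_corpus, epochs=200)
    return model
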