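"""Seq2seq model: gradient correctness, training dynamics, encode/decode."""

import numpy as np
import pytest

from latentmol import ModelConfig, Seq2SeqModel
from latentmol.errors import ConfigurationError
from latentmol.selfies_coder import SequenceAlphabet, vectorize


@pytest.fixture
def tiny_setup():
    alpha = SequenceAlphabet(
        token_to_char={"[C]": "a", "[O]": "b", "[N]": "c"}, embed=7)
    model = Seq2SeqModel(alpha, ModelConfig(lstm_units=5, rng_seed=3))
    X = np.stack([vectorize("abc", alpha).matrix,
                  vectorize("ca", alpha).matrix])
    return alpha, model, X


def test_backprop_matches_finite_differences(tiny_setup):
    """Analytic BPTT gradients agree with central finite differences."""
    _, model, X = tiny_setup
    loss, cache = model._forward_loss(X)
    grads = model._backward(cache)
    rng = np.random.default_rng(0)
    eps = 1e-6
    for p, g in zip(model._params, grads):
        for _ in range(4):
            idx = tuple(rng.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp = model._forward_loss(X)[0]
            p[idx] = orig - eps
            lm = model._forward_loss(X)[0]
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert numeric == pytest.approx(g[idx], rel=1e-3, abs=1e-7)


def test_decoder_emissions_are_distributions(tiny_setup):
    alpha, model, X = tiny_setup
    state = model.encode(X[0])
    x0 = np.zeros((1, alpha.size))
    x0[0, alpha.char_to_index["!"]] = 1.0
    h, c = state.h[None], state.c[None]
    probs, _, _ = model.step_probabilities(x0, h, c)
    assert np.all(probs >= 0)
    assert probs.sum() == pytest.approx(1.0)


def test_training_loss_decreases(alphabet, onehot_corpus):
    model = Seq2SeqModel(alphabet, ModelConfig(rng_seed=1))
    train, val = onehot_corpus[:60], onehot_corpus[60:80]
    history = model.fit(train, val, epochs=12)
    assert history.loss[-1] < history.loss[0]
    assert history.val_loss[-1] < history.val_loss[0]
    assert all(l >= 0 for l in history.loss + history.val_loss)


def test_empty_training_set_rejected(alphabet):
    model = Seq2SeqModel(alphabet)
    with pytest.raises(ConfigurationError):
        model.fit([])


def test_alphabet_mismatch_rejected(alphabet, onehot_corpus):
    other = SequenceAlphabet(token_to_char={"[C]": "a"}, embed=4)
    model = Seq2SeqModel(other)
    with pytest.raises(ConfigurationError):
        model.fit(onehot_corpus[:2])


def test_encode_is_deterministic_with_correct_shape(
        overfit_model, onehot_corpus):
    s1 = overfit_model.encode(onehot_corpus[0])
    s2 = overfit_model.encode(onehot_corpus[0])
    units = overfit_model.config.lstm_units
    assert s1.h.shape == (units,) and s1.c.shape == (units,)
    assert np.array_equal(s1.h, s2.h) and np.array_equal(s1.c, s2.c)


def test_distinct_molecules_get_distinct_states(
        overfit_model, onehot_corpus):
    s1 = overfit_model.encode(onehot_corpus[0])
    s2 = overfit_model.encode(onehot_corpus[1])
    assert not np.array_equal(s1.h, s2.h)


def test_decoded_length_respects_stop_rule(overfit_model, onehot_corpus):
    for onehot in onehot_corpus[:20]:
        seq = overfit_model.decode_states(overfit_model.encode(onehot))
        assert len(seq) <= overfit_model.alphabet.embed - 2


def test_single_molecule_overfits_to_exact_identity():
    alpha = SequenceAlphabet(
        token_to_char={"[C]": "a", "[O]": "b"}, embed=8)
    model = Seq2SeqModel(alpha, ModelConfig(
        lstm_units=32, batch_size=1, rng_seed=2))
    seq = "abab"
    model.fit([vectorize(seq, alpha)], epochs=120)
    assert model.decode_states(
        model.encode(vectorize(seq, alpha))) == seq


def test_checkpoint_round_trip(tmp_path, overfit_model, onehot_corpus):
    overfit_model.save(tmp_path / "ckpt")
    reloaded = Seq2SeqModel.load(tmp_path / "ckpt")
    for onehot in onehot_corpus[:5]:
        assert reloaded.decode_states(reloaded.encode(onehot)) \
            == overfit_model.decode_states(overfit_model.encode(onehot))
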