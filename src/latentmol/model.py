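"""Recurrent encoder-decoder over one-hot molecular sequences.

A single-layer LSTM encoder compresses the padded one-hot sequence of a
molecule into its final hidden/cell state pair — the molecule's *latent
state*.  A second LSTM, initialized with that state, is trained with
teacher forcing to re-emit the sequence character by character under a
categorical cross-entropy loss.  At prediction time the decoder starts
from the ``!`` marker and greedily appends the argmax character until the
``E`` marker appears; sampling diversity comes from perturbing the latent
state, not from the emissions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from ._lstm import Adam, Dense, LSTMCell, cross_entropy, softmax
from .errors import ConfigurationError, SequenceLengthError
from .selfies_coder import OneHotSequence, SequenceAlphabet, vectorize


@dataclass
class ModelConfig:
    """Architecture and optimization settings.

    The unit count, batch size and learning rate are implementation
    choices (exposed here); the epoch budget defaults to the fixed
    200-epoch training schedule.
    """

    lstm_units: int = 128
    max_epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 1e-2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.lstm_units < 1 or self.batch_size < 1:
            raise ValueError("lstm_units and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class LatentState:
    """Encoder hidden/cell state pair; the sampling anchor of a molecule."""

    h: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        if self.h.shape != self.c.shape:
            raise ValueError("h and c must share a shape")
        if not (np.isfinite(self.h).all() and np.isfinite(self.c).all()):
            raise ValueError("latent state entries must be finite")


@dataclass
class TrainingHistory:
    """Per-epoch training and validation cross-entropy."""

    loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)


def _stack(dataset: Sequence[OneHotSequence]) -> np.ndarray:
    return np.stack([d.matrix for d in dataset])


class Seq2SeqModel:
    """LSTM encoder-decoder bound to one :class:`SequenceAlphabet`."""

    def __init__(self, alphabet: SequenceAlphabet,
                 config: ModelConfig | None = None) -> None:
        self.alphabet = alphabet
        self.config = config or ModelConfig()
        rng = np.random.default_rng(self.config.rng_seed)
        V, H = alphabet.size, self.config.lstm_units
        self.encoder = LSTMCell(V, H, rng)
        self.decoder = LSTMCell(V, H, rng)
        self.head = Dense(H, V, rng)
        self._params = (self.encoder.params + self.decoder.params
                        + self.head.params)

    # -- training -----------------------------------------------------------

    def _check(self, dataset: Sequence[OneHotSequence]) -> None:
        if len(dataset) == 0:
            raise ConfigurationError("empty dataset")
        shape = (self.alphabet.embed, self.alphabet.size)
        for d in dataset:
            if d.matrix.shape != shape:
                raise ConfigurationError(
                    f"one-hot shape {d.matrix.shape} does not match the "
                    f"alphabet ({shape}); datasets must share one alphabet")

    def _forward_loss(self, X: np.ndarray):
        """Teacher-forced forward pass; X is (B, T, V)."""
        dec_in, target = X[:, :-1, :], X[:, 1:, :]
        B, H = X.shape[0], self.config.lstm_units
        h0 = np.zeros((B, H))
        _, h, c, enc_caches = self.encoder.forward(X, h0, h0.copy())
        hs, _, _, dec_caches = self.decoder.forward(dec_in, h, c)
        logits = self.head.forward(hs)
        probs = softmax(logits)
        loss = cross_entropy(probs, target)
        return loss, (X, dec_in, target, enc_caches, dec_caches, hs, probs)

    def _backward(self, cache) -> list[np.ndarray]:
        X, dec_in, target, enc_caches, dec_caches, hs, probs = cache
        B, Tm1, _ = target.shape
        d_logits = (probs - target) / (B * Tm1)
        head_grads, d_hs = self.head.backward(hs, d_logits)
        zeros = np.zeros((B, self.config.lstm_units))
        dec_grads, dh0, dc0 = self.decoder.backward(
            dec_caches, d_hs, zeros, zeros.copy())
        enc_grads, _, _ = self.encoder.backward(enc_caches, None, dh0, dc0)
        return enc_grads + dec_grads + head_grads

    def fit(self, train: Sequence[OneHotSequence],
            validation: Sequence[OneHotSequence] = (),
            epochs: int | None = None) -> TrainingHistory:
        """Train in place; returns per-epoch loss history."""
        self._check(train)
        if validation:
            self._check(validation)
        X = _stack(train)
        Xval = _stack(validation) if validation else None
        n_epochs = epochs if epochs is not None else self.config.max_epochs
        rng = np.random.default_rng(self.config.rng_seed + 1)
        opt = Adam(self._params, lr=self.config.learning_rate)
        history = TrainingHistory()
        B = self.config.batch_size
        for _ in range(n_epochs):
            order = rng.permutation(len(X))
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(X), B):
                batch = X[order[start:start + B]]
                loss, cache = self._forward_loss(batch)
                opt.step(self._backward(cache))
                epoch_loss += loss
                n_batches += 1
            history.loss.append(epoch_loss / n_batches)
            if Xval is not None:
                history.val_loss.append(self._forward_loss(Xval)[0])
        return history

    # -- inference ----------------------------------------------------------

    def encode(self, onehot: OneHotSequence | np.ndarray) -> LatentState:
        """Map one one-hot sequence to its latent state (deterministic)."""
        matrix = onehot.matrix if isinstance(onehot, OneHotSequence) else onehot
        if matrix.shape != (self.alphabet.embed, self.alphabet.size):
            raise ConfigurationError(
                f"sequence shape {matrix.shape} does not match alphabet")
        H = self.config.lstm_units
        h0 = np.zeros((1, H))
        _, h, c, _ = self.encoder.forward(matrix[None, :, :], h0, h0.copy())
        return LatentState(h=h[0].copy(), c=c[0].copy())

    def encode_sequence_text(self, sequence: str) -> LatentState:
        """Convenience: molecular sequence text -> latent state."""
        return self.encode(vectorize(sequence, self.alphabet))

    def decode_states(self, state: LatentState) -> str:
        """Greedy character-by-character decoding of a latent state.

        Starts from the ``!`` marker, appends the argmax character at each
        step, and stops at ``E`` or after ``embed - 2`` characters.  The
        returned molecular sequence excludes both markers.
        """
        if not (np.isfinite(state.h).all() and np.isfinite(state.c).all()):
            raise ValueError("non-finite latent state")
        if state.h.shape != (self.config.lstm_units,):
            raise ConfigurationError("latent state size mismatch")
        h, c = state.h[None, :].copy(), state.c[None, :].copy()
        x = np.zeros((1, self.alphabet.size))
        x[0, self.alphabet.char_to_index[self.alphabet.start_char]] = 1.0
        chars: list[str] = []
        for _ in range(self.alphabet.embed - 2):
            h, c, _ = self.decoder.step(x, h, c)
            probs = softmax(self.head.forward(h))
            idx = int(probs[0].argmax())
            char = self.alphabet.index_to_char[idx]
            if char == self.alphabet.end_char:
                break
            chars.append(char)
            x = np.zeros((1, self.alphabet.size))
            x[0, idx] = 1.0
        return "".join(chars)

    def step_probabilities(self, x: np.ndarray, h: np.ndarray,
                           c: np.ndarray):
        """One decoder step; returns (probs, h', c').  Used by samplers."""
        h2, c2, _ = self.decoder.step(x, h, c)
        return softmax(self.head.forward(h2)), h2, c2

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Checkpoint: config + alphabet (JSON) and weights (npz)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(
            json.dumps(asdict(self.config), indent=2) + "\n")
        self.alphabet.save(directory / "alphabet.json")
        arrays = {f"p{i}": p for i, p in enumerate(self._params)}
        np.savez(directory / "weights.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path) -> "Seq2SeqModel":
        directory = Path(directory)
        config = ModelConfig(**json.loads(
            (directory / "config.json").read_text()))
        alphabet = SequenceAlphabet.load(directory / "alphabet.json")
        model = cls(alphabet, config)
        with np.load(directory / "weights.npz") as data:
            for i, p in enumerate(model._params):
                p[:] = data[f"p{i}"]
        return model
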