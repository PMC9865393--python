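"""SELFIES tokens <-> mono-character sequences <-> one-hot arrays.

The sequence model consumes fixed-length one-hot arrays, so each SELFIES
token is first mapped to a single printable character ("molecular
sequence"), then characters to integer indices, then indices to one-hot
rows.  Two marker characters frame every sequence: ``!`` starts it and
``E`` ends it; ``E`` doubles as the padding character, so rows beyond the
end of a molecule keep encoding ``E``.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import CapacityError, SequenceLengthError, VocabularyError
from .selfies_lang import alphabet_of, tokenize

START_CHAR = "!"
END_CHAR = "E"

#: Characters available for molecule tokens: printable, minus the markers
#: and whitespace.
_CHAR_POOL = "".join(
    c for c in string.ascii_letters + string.digits + string.punctuation
    if c not in (START_CHAR, END_CHAR))

#: Default cap on the total padded sequence length (markers included).
DEFAULT_EMBED_CAP = 65

_FORMAT_VERSION = 1


@dataclass
class SequenceAlphabet:
    """Bijections between SELFIES tokens, characters and integer indices.

    ``embed`` is the padded sequence length every one-hot array uses; it
    must be at least the longest training molecular sequence plus the two
    markers.
    """

    token_to_char: dict[str, str]
    embed: int
    start_char: str = START_CHAR
    end_char: str = END_CHAR
    char_to_token: dict[str, str] = field(init=False)
    char_to_index: dict[str, int] = field(init=False)
    index_to_char: dict[int, str] = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.token_to_char.values())) != len(self.token_to_char):
            raise ValueError("token_to_char is not a bijection")
        if self.start_char in self.token_to_char.values() \
                or self.end_char in self.token_to_char.values():
            raise ValueError("marker characters must not encode tokens")
        self.char_to_token = {c: t for t, c in self.token_to_char.items()}
        chars = [self.start_char, self.end_char] + sorted(
            self.token_to_char.values())
        self.char_to_index = {c: i for i, c in enumerate(chars)}
        self.index_to_char = {i: c for c, i in self.char_to_index.items()}

    @property
    def size(self) -> int:
        """Alphabet size including the two markers."""
        return len(self.char_to_index)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {"format_version": _FORMAT_VERSION,
                   "start_char": self.start_char, "end_char": self.end_char,
                   "embed": self.embed, "token_to_char": self.token_to_char}
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SequenceAlphabet":
        payload = json.loads(text)
        return cls(token_to_char=payload["token_to_char"],
                   embed=payload["embed"],
                   start_char=payload["start_char"],
                   end_char=payload["end_char"])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SequenceAlphabet":
        return cls.from_json(Path(path).read_text())


def build_alphabet(corpus: Sequence[str], embed: int | None = None,
                   embed_cap: int = DEFAULT_EMBED_CAP) -> SequenceAlphabet:
    """Build the alphabet of a SELFIES corpus.

    Characters are assigned to tokens in sorted-token order from a fixed
    printable pool, so the alphabet depends only on the corpus token *set*.
    Default ``embed`` is the longest molecular sequence + 2 markers, capped
    at ``embed_cap``.
    """
    if not corpus:
        raise ValueError("empty corpus")
    tokens = sorted(alphabet_of(corpus))
    if len(tokens) > len(_CHAR_POOL):
        raise CapacityError(
            f"{len(tokens)} distinct tokens exceed the "
            f"{len(_CHAR_POOL)}-character pool")
    token_to_char = {t: _CHAR_POOL[i] for i, t in enumerate(tokens)}
    if embed is None:
        longest = max(len(tokenize(s)) for s in corpus)
        embed = min(longest + 2, embed_cap)
    return SequenceAlphabet(token_to_char=token_to_char, embed=embed)


def encode_sequence(selfies: str, alphabet: SequenceAlphabet) -> str:
    """SELFIES -> molecular sequence (one character per token)."""
    chars = []
    for token in tokenize(selfies):
        try:
            chars.append(alphabet.token_to_char[token])
        except KeyError:
            raise VocabularyError(f"token {token} absent from alphabet")
    return "".join(chars)


def decode_sequence(sequence: str, alphabet: SequenceAlphabet) -> str:
    """Molecular sequence -> SELFIES."""
    tokens = []
    for char in sequence:
        try:
            tokens.append(alphabet.char_to_token[char])
        except KeyError:
            raise VocabularyError(f"character {char!r} absent from alphabet")
    return "".join(tokens)


@dataclass(frozen=True)
class OneHotSequence:
    """A padded one-hot matrix (embed x alphabet size) plus the raw length."""

    matrix: np.ndarray
    length: int

    def __post_init__(self) -> None:
        if not np.array_equal(self.matrix.sum(axis=1),
                              np.ones(self.matrix.shape[0])):
            raise ValueError("one-hot rows must sum to 1")


def vectorize(sequence: str, alphabet: SequenceAlphabet) -> OneHotSequence:
    """Molecular sequence -> one-hot array ``!<sequence>EEE...`` of length embed."""
    if len(sequence) + 2 > alphabet.embed:
        raise SequenceLengthError(
            f"sequence of {len(sequence)} characters exceeds the "
            f"embed budget of {alphabet.embed} (2 markers included)")
    padded = (alphabet.start_char + sequence
              + alphabet.end_char * (alphabet.embed - len(sequence) - 1))
    matrix = np.zeros((alphabet.embed, alphabet.size), dtype=np.float64)
    for row, char in enumerate(padded):
        try:
            matrix[row, alphabet.char_to_index[char]] = 1.0
        except KeyError:
            raise VocabularyError(f"character {char!r} absent from alphabet")
    return OneHotSequence(matrix=matrix, length=len(sequence))


def devectorize(onehot: OneHotSequence | np.ndarray,
                alphabet: SequenceAlphabet) -> str:
    """Invert :func:`vectorize`: strip markers and padding."""
    matrix = onehot.matrix if isinstance(onehot, OneHotSequence) else onehot
    chars = [alphabet.index_to_char[int(i)] for i in matrix.argmax(axis=1)]
    if chars and chars[0] == alphabet.start_char:
        chars = chars[1:]
    out = []
    for c in chars:
        if c == alphabet.end_char:
            break
        out.append(c)
    return "".join(out)
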