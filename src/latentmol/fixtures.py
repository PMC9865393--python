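"""Download-free synthetic molecule corpora.

Random SELFIES sampling over a restricted drug-like token alphabet yields
valid molecules by construction, which makes it possible to exercise the
entire pipeline — corpus preparation, model training, generation,
filtering, similarity and mock docking — without any external database.
The default token alphabet is kept small and organic so fixture molecules
stay loosely drug-like; the default length window matches the 30-50-token
corpus the preparation stage selects.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from rdkit import Chem

from .dataset_prep import MoleculeRecord
from .errors import DecodeError
from .scoring_filters import DescriptorPanel, normalize_and_rank
from .selfies_lang import _Graph, _derive, decode, tokenize

#: Restricted token alphabet for fixture molecules.
DEFAULT_TOKEN_ALPHABET = (
    "[C]", "[N]", "[O]", "[S]", "[F]", "[=C]", "[=N]", "[=O]",
    "[Branch1]", "[Ring1]", "[Ring2]",
)


@dataclass
class FixtureSpec:
    """Conditions of a synthetic corpus."""

    n_molecules: int = 1000
    token_alphabet: tuple[str, ...] = DEFAULT_TOKEN_ALPHABET
    length_range: tuple[int, int] = (30, 50)
    rng_seed: int = 0
    #: reject draws whose derivation terminated early: the decoded molecule
    #: must realize at least this fraction of the token count as heavy
    #: atoms, keeping SELFIES length roughly proportional to molecule size
    min_atom_fraction: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("length_range must satisfy 1 <= lo <= hi")
        for token in self.token_alphabet:
            try:
                decode(token * 3)
            except DecodeError as exc:
                raise ValueError(f"invalid token {token!r} in alphabet: "
                                 f"{exc}") from exc


def random_corpus(spec: FixtureSpec) -> list[MoleculeRecord]:
    """Sample unique valid molecules by uniform random SELFIES strings.

    Each record's SELFIES is the sampled token string itself (it decodes
    to the record's canonical generic SMILES); records are deduplicated on
    canonical SMILES and sampled until ``n_molecules`` unique ones exist.
    """
    rng = random.Random(spec.rng_seed)
    lo, hi = spec.length_range
    seen: set[str] = set()
    records: list[MoleculeRecord] = []
    # guard against pathological alphabets that mostly decode to nothing
    max_attempts = 200 * spec.n_molecules + 1000
    attempts = 0
    while len(records) < spec.n_molecules and attempts < max_attempts:
        attempts += 1
        length = rng.randint(lo, hi)
        selfies = "".join(rng.choices(spec.token_alphabet, k=length))
        graph = _Graph()
        _derive(iter(tokenize(selfies)), graph, None, None)
        if len(graph.elements) < spec.min_atom_fraction * length:
            continue
        smiles = Chem.MolToSmiles(graph.to_mol())
        if not smiles or smiles in seen:
            continue
        seen.add(smiles)
        records.append(MoleculeRecord(
            smiles_raw=smiles, smiles_generic=smiles, selfies=selfies,
            token_length=len(tokenize(selfies)), source_tag="fixture"))
    if len(records) < spec.n_molecules:
        raise ValueError("could not reach the requested corpus size; "
                         "alphabet too restrictive")
    return records


def length_histogram(records: Sequence[MoleculeRecord]) -> dict[int, int]:
    """Token-length distribution of a corpus (for eyeballing the window)."""
    return dict(sorted(Counter(r.token_length for r in records).items()))


def make_seed_actives(ranked_smiles: Sequence[str], n: int = 5) -> list[str]:
    """Pick seed molecules spanning a ranked (descending score) corpus.

    The selection rule takes two from the top, two from the middle (the
    two central ranks) and the last one; smaller ``n`` degrades to the
    top molecule (n=1) or top + last (n=2).
    """
    N = len(ranked_smiles)
    if N < n:
        raise ValueError(f"corpus of {N} is smaller than n={n}")
    if n == 1:
        return [ranked_smiles[0]]
    if n == 2:
        return [ranked_smiles[0], ranked_smiles[-1]]
    n_mid = n - 3
    start = (N - n_mid) // 2
    idx = [0, 1, *range(start, start + n_mid), N - 1]
    return [ranked_smiles[i] for i in idx]


def rank_corpus_by_my_score(
        panels: dict[str, DescriptorPanel]) -> list[str]:
    """Descending-My-score ordering of a scored corpus."""
    return [k for k, _ in normalize_and_rank(panels)]


def make_easy_hard_sets(rng_seed: int = 0, n_each: int = 40,
                        ) -> tuple[list[str], list[str]]:
    """Training pair for the synthesizability table.

    Easy: small linear or singly-branched chains of C/N/O (the sort of
    skeleton any catalogue synthesis reaches).  Hard: dense polycyclic
    molecules obtained from ring-heavy random SELFIES.  The sets are
    disjoint by canonical SMILES and reproducible for a fixed seed.
    """
    rng = random.Random(rng_seed)
    easy: list[str] = []
    seen: set[str] = set()
    chain_tokens = ("[C]", "[C]", "[C]", "[N]", "[O]")
    attempts = 0
    while len(easy) < n_each and attempts < 100 * n_each:
        attempts += 1
        length = rng.randint(2, 8)
        selfies = "".join(rng.choices(chain_tokens, k=length))
        smiles = decode(selfies)
        if smiles and smiles not in seen:
            seen.add(smiles)
            easy.append(smiles)

    ring_tokens = ("[C]", "[C]", "[=C]", "[N]", "[O]", "[S]",
                   "[Ring1]", "[Ring1]", "[Ring2]", "[Branch1]")
    hard: list[str] = []
    attempts = 0
    while len(hard) < n_each and attempts < 200 * n_each:
        attempts += 1
        length = rng.randint(25, 45)
        selfies = "".join(rng.choices(ring_tokens, k=length))
        smiles = decode(selfies)
        if smiles and smiles not in seen and smiles.count("1") >= 2:
            seen.add(smiles)
            hard.append(smiles)
    if len(easy) < n_each or len(hard) < n_each:
        raise ValueError("could not build easy/hard sets of requested size")
    return easy, hard
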