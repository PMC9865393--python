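"""Candidate generation by latent-space perturbation ("tensor scaling").

Each seed molecule is encoded to its latent state; random noise of a given
amplitude is added to both the hidden and cell vectors; the perturbed state
is decoded greedily back to a molecular sequence, then through the alphabet
to SELFIES and on to canonical SMILES.  Because every decoded SELFIES
string is a valid molecule, the raw candidate list is 100% valid by
construction; duplicates are removed on canonical SMILES.
"""

from __future__ import annotations

import json
import urllib.error
import urllib.request
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .errors import SequenceLengthError
from .model import LatentState, Seq2SeqModel
from .selfies_coder import decode_sequence, encode_sequence, vectorize
from .selfies_lang import selfies_to_smiles, smiles_to_selfies


@dataclass
class GenerationSpec:
    """Sampling conditions: noise amplitudes and samples per seed."""

    amplitudes: tuple[float, ...] = (0.1, 0.2)
    samples_per_seed: int = 20
    rng_seed: int = 0
    noise: Literal["gaussian", "uniform"] = "gaussian"

    def __post_init__(self) -> None:
        if self.samples_per_seed < 1:
            raise ValueError("samples_per_seed must be >= 1")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be non-negative")


@dataclass(frozen=True)
class Candidate:
    """A generated molecule with its provenance."""

    smiles: str
    selfies: str
    seed_id: str
    amplitude: float
    pubchem_cid: int | None = None


def perturb_latent(state: LatentState, amplitude: float,
                   rng: np.random.Generator,
                   noise: str = "gaussian") -> LatentState:
    """Add zero-mean noise with per-component scale = amplitude.

    ``gaussian`` draws N(0, amplitude^2); ``uniform`` draws from
    [-a*sqrt(3), a*sqrt(3)] so the standard deviation is also the
    amplitude.  Amplitude 0 returns the state unchanged.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if amplitude == 0:
        return state
    if noise == "gaussian":
        dh = rng.normal(0.0, amplitude, size=state.h.shape)
        dc = rng.normal(0.0, amplitude, size=state.c.shape)
    elif noise == "uniform":
        half = amplitude * np.sqrt(3.0)
        dh = rng.uniform(-half, half, size=state.h.shape)
        dc = rng.uniform(-half, half, size=state.c.shape)
    else:
        raise ValueError(f"unknown noise family {noise!r}")
    return LatentState(h=state.h + dh, c=state.c + dc)


def generate(seeds: Sequence[str], model: Seq2SeqModel,
             spec: GenerationSpec | None = None,
             ) -> tuple[list[Candidate], list[Candidate]]:
    """Sample candidates around each seed SMILES at every amplitude.

    Returns ``(raw, unique)``: the raw list holds
    ``len(seeds) * samples_per_seed`` candidates per amplitude; the unique
    list is deduplicated on canonical SMILES per amplitude first, then
    across amplitudes.  Seed reconstructions are kept, not filtered.
    """
    spec = spec or GenerationSpec()
    rng = np.random.default_rng(spec.rng_seed)
    alphabet = model.alphabet

    anchors = []
    for i, smiles in enumerate(seeds):
        selfies = smiles_to_selfies(smiles)
        sequence = encode_sequence(selfies, alphabet)
        if len(sequence) + 2 > alphabet.embed:
            raise SequenceLengthError(
                f"seed {smiles!r} exceeds the embed budget")
        state = model.encode(vectorize(sequence, alphabet))
        anchors.append((f"seed{i}", state))

    raw: list[Candidate] = []
    unique: list[Candidate] = []
    seen_all: set[str] = set()
    for amplitude in spec.amplitudes:
        seen_amp: set[str] = set()
        unique_amp: list[Candidate] = []
        for seed_id, state in anchors:
            for _ in range(spec.samples_per_seed):
                perturbed = perturb_latent(state, amplitude, rng, spec.noise)
                sequence = model.decode_states(perturbed)
                selfies = decode_sequence(sequence, alphabet)
                smiles = selfies_to_smiles(selfies)
                cand = Candidate(smiles=smiles, selfies=selfies,
                                 seed_id=seed_id, amplitude=amplitude)
                raw.append(cand)
                if smiles and smiles not in seen_amp:
                    seen_amp.add(smiles)
                    unique_amp.append(cand)
        for cand in unique_amp:
            if cand.smiles not in seen_all:
                seen_all.add(cand.smiles)
                unique.append(cand)
    return raw, unique


# ---------------------------------------------------------------------------
# optional PubChem annotation (network-gated; never filters)

_PUG_URL = ("https://pubchem.ncbi.nlm.nih.gov/rest/pug/compound/smiles/"
            "{}/cids/JSON")


def lookup_pubchem(candidates: Sequence[Candidate],
                   timeout: float = 5.0) -> list[Candidate]:
    """Annotate candidates with PubChem CIDs where the service is reachable.

    Entirely offline-safe: on any network failure a warning is emitted and
    the candidates are returned unannotated.  Annotation never filters.
    """
    out = []
    for cand in candidates:
        cid = None
        try:
            from urllib.parse import quote
            with urllib.request.urlopen(_PUG_URL.format(quote(cand.smiles)),
                                        timeout=timeout) as resp:
                payload = json.load(resp)
            cids = payload.get("IdentifierList", {}).get("CID", [])
            cid = int(cids[0]) if cids and cids[0] else None
        except Exception as exc:  # noqa: BLE001 - any failure is a no-op
            warnings.warn(f"PubChem lookup unavailable ({exc}); "
                          "candidates left unannotated", stacklevel=2)
            return list(candidates)
        out.append(replace(cand, pubchem_cid=cid))
    return out
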