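"""Fingerprint-based Tanimoto similarity.

Molecules are hashed into path-based binary fingerprints (the RDKit
daylight-like fingerprint); the Tanimoto coefficient of two fingerprints
is |intersection| / |union| of their set bits — 1 for identical bit
patterns, 0 when no bits are shared.  Pairwise matrices between molecule
sets come with min/max/mean summaries and histogram bins for plotting.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .errors import ParseError


@dataclass(frozen=True)
class FingerprintParams:
    """Path-based fingerprint settings (defaults: paths up to 7 bonds,
    2048 bits)."""

    max_path: int = 7
    n_bits: int = 2048


@dataclass(frozen=True)
class Fingerprint:
    """A binary fingerprint as its set of on-bit positions."""

    bitset: frozenset[int]
    n_bits: int

    def __post_init__(self) -> None:
        if any(b < 0 or b >= self.n_bits for b in self.bitset):
            raise ValueError("bit positions must lie below n_bits")


def fingerprint(smiles: str,
                params: FingerprintParams | None = None) -> Fingerprint:
    """RDKit path fingerprint of a molecule (deterministic per molecule)."""
    params = params or FingerprintParams()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(
        maxPath=params.max_path, fpSize=params.n_bits)
    bv = gen.GetFingerprint(mol)
    bits = frozenset(bv.GetOnBits())
    if not bits and mol.GetNumAtoms() > 0:
        # single-atom molecules have no bond paths; give them one
        # identity bit so distinct atoms stay distinguishable
        digest = hashlib.sha256(
            Chem.MolToSmiles(mol).encode()).digest()
        bits = frozenset({int.from_bytes(digest[:4], "big")
                          % params.n_bits})
    return Fingerprint(bitset=bits, n_bits=params.n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a & b| / |a | b|; 1.0 by convention when both are empty."""
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprint lengths differ")
    union = a.bitset | b.bitset
    if not union:
        return 1.0
    return len(a.bitset & b.bitset) / len(union)


@dataclass
class SimilarityReport:
    """Pairwise |A| x |B| Tanimoto matrix with summaries."""

    matrix: np.ndarray
    min: float
    max: float
    mean: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray

    def to_summary_dict(self) -> dict[str, float]:
        return {"min": self.min, "max": self.max, "mean": self.mean}

    def save_matrix_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.matrix, delimiter=",", fmt="%.6f")

    def save_summary_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_summary_dict(), indent=2) + "\n")

    def save_hist_csv(self, path: str | Path) -> None:
        rows = np.column_stack([self.hist_edges[:-1], self.hist_edges[1:],
                                self.hist_counts])
        np.savetxt(path, rows, delimiter=",", fmt="%.6f",
                   header="bin_lo,bin_hi,count", comments="")


def similarity_report(set_a: Sequence[str], set_b: Sequence[str],
                      params: FingerprintParams | None = None,
                      n_bins: int = 20) -> SimilarityReport:
    """All-pairs Tanimoto between two SMILES sets.

    Summaries run over all ordered pairs (every molecule of A against
    every molecule of B).
    """
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    fps_a = [fingerprint(s, params) for s in set_a]
    fps_b = [fingerprint(s, params) for s in set_b]
    matrix = np.array([[tanimoto(fa, fb) for fb in fps_b] for fa in fps_a])
    counts, edges = np.histogram(matrix.ravel(), bins=n_bins,
                                 range=(0.0, 1.0))
    return SimilarityReport(matrix=matrix, min=float(matrix.min()),
                            max=float(matrix.max()),
                            mean=float(matrix.mean()),
                            hist_counts=counts, hist_edges=edges)
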