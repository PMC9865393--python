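"""Training-corpus preparation.

Raw SMILES collections are canonicalized to their generic (stereo-free)
form, translated into SELFIES, filtered by SELFIES token length and element
whitelist, deduplicated, and split into training/validation partitions.
The stage counts of the filter cascade are reported so corpus reductions
are auditable.
"""

from __future__ import annotations

import csv
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem

from .errors import EmptyCorpusError, ParseError
from .selfies_lang import (canonicalize_generic, selfies_to_smiles,
                           smiles_to_selfies, token_length)

#: Common drug-like elements; rare heteroatoms (Sn, Se, B, P, ...) are
#: excluded by default but the whitelist is configurable.
DEFAULT_ALLOWED_ELEMENTS = frozenset(
    {"H", "C", "N", "O", "S", "F", "Cl", "Br", "I"})


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule flowing through the pipeline.

    ``selfies`` always decodes to a molecule whose canonical generic SMILES
    equals ``smiles_generic``; ``token_length`` counts bracketed SELFIES
    units.
    """

    smiles_raw: str
    smiles_generic: str
    selfies: str
    token_length: int
    source_tag: str = ""

    @classmethod
    def from_smiles(cls, smiles: str, source_tag: str = "") -> "MoleculeRecord":
        generic = canonicalize_generic(smiles)
        selfies = smiles_to_selfies(generic)
        return cls(smiles_raw=smiles, smiles_generic=generic, selfies=selfies,
                   token_length=token_length(selfies), source_tag=source_tag)

    @property
    def elements(self) -> set[str]:
        mol = Chem.MolFromSmiles(self.smiles_generic)
        if mol is None:
            raise ParseError(self.smiles_generic)
        return {a.GetSymbol() for a in mol.GetAtoms()}


@dataclass
class CorpusSpec:
    """Filtering and splitting parameters for corpus preparation."""

    length_min: int = 30
    length_max: int = 50
    allowed_elements: frozenset[str] = DEFAULT_ALLOWED_ELEMENTS
    validation_fraction: float = 0.10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.length_min > self.length_max:
            raise ValueError("length_min must not exceed length_max")


@dataclass
class FilterReport:
    """Per-stage survivor counts of the corpus filter cascade."""

    n_input: int
    n_after_length: int
    n_after_elements: int
    n_after_dedup: int

    def to_dict(self) -> dict[str, int]:
        return dict(input=self.n_input, after_length=self.n_after_length,
                    after_elements=self.n_after_elements,
                    after_dedup=self.n_after_dedup)


def apply_filters(records: Sequence[MoleculeRecord],
                  spec: CorpusSpec) -> tuple[list[MoleculeRecord], FilterReport]:
    """Length window (inclusive), element whitelist, dedup on canonical SMILES.

    Raises :class:`EmptyCorpusError` when nothing survives.
    """
    n_input = len(records)
    by_length = [r for r in records
                 if spec.length_min <= r.token_length <= spec.length_max]
    by_elements = [r for r in by_length
                   if r.elements <= spec.allowed_elements]
    seen: set[str] = set()
    deduped: list[MoleculeRecord] = []
    for r in by_elements:
        if r.smiles_generic not in seen:
            seen.add(r.smiles_generic)
            deduped.append(r)
    report = FilterReport(n_input, len(by_length), len(by_elements),
                          len(deduped))
    if not deduped:
        raise EmptyCorpusError("no records survived the filter cascade")
    return deduped, report


def train_val_split(records: Sequence[MoleculeRecord], spec: CorpusSpec,
                    ) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Random disjoint/exhaustive split; |validation| = round(fraction*n).

    Reproducible for a fixed ``spec.rng_seed``.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 records to split")
    n_val = round(spec.validation_fraction * len(records))
    order = list(range(len(records)))
    random.Random(spec.rng_seed).shuffle(order)
    val_idx = set(order[:n_val])
    train = [r for i, r in enumerate(records) if i not in val_idx]
    val = [r for i, r in enumerate(records) if i in val_idx]
    return train, val


def prepare_corpus(smiles_list: Iterable[str], spec: CorpusSpec,
                   source_tag: str = "", skip_unparsable: bool = True,
                   ) -> tuple[list[MoleculeRecord], list[MoleculeRecord],
                              FilterReport]:
    """Full preparation: records -> filters -> split.

    Unparsable or grammar-unsupported SMILES are skipped (counted as lost
    before the cascade) unless ``skip_unparsable`` is false.
    """
    records = []
    for s in smiles_list:
        try:
            records.append(MoleculeRecord.from_smiles(s, source_tag))
        except ParseError:
            if not skip_unparsable:
                raise
        except Exception:
            if not skip_unparsable:
                raise
    survivors, report = apply_filters(records, spec)
    train, val = train_val_split(survivors, spec)
    return train, val, report


# ---------------------------------------------------------------------------
# I/O

def read_smi(path: str | Path) -> list[str]:
    """Read an SMI file: one SMILES per line, optional tab-separated id."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split("\t")[0].split()[0])
    return out


def read_smiles_csv(path: str | Path, smiles_column: str = "smiles") -> list[str]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if smiles_column not in (reader.fieldnames or []):
            raise ValueError(f"column {smiles_column!r} absent from {path}")
        return [row[smiles_column] for row in reader]


def write_corpus_csv(path: str | Path, train: Sequence[MoleculeRecord],
                     val: Sequence[MoleculeRecord]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["smiles_generic", "selfies", "token_length",
                        "partition"])
        for part, recs in (("train", train), ("validation", val)):
            for r in recs:
                writer.writerow([r.smiles_generic, r.selfies,
                                r.token_length, part])


def write_report_json(path: str | Path, report: FilterReport) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
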