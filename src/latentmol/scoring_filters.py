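"""Drug-likeness discriminators, synthesizability scoring and ranking.

Three discriminators sieve generated candidates:

1. QED (quantitative estimate of drug-likeness) must reach 0.5;
2. Lipinski's rule of 5 (MW <= 500, logP <= 5, HBD <= 5, HBA <= 10),
   strict by default with a configurable violation allowance;
3. a Bernoulli naive-Bayes fragment score (SYBA-style): the sum over the
   molecule's distinct circular fragments of a log-likelihood ratio learned
   from an easy- vs hard-to-synthesize training pair; scores below 0 are
   rejected.

Survivors are ranked by "My score": 100 times the arithmetic mean of the
min-max-normalized QED and synthesizability scores, computed over an
explicit reference set.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED
from rdkit.Chem import rdFingerprintGenerator

from .errors import ParseError

QED_THRESHOLD = 0.5
SYN_THRESHOLD = 0.0


@dataclass(frozen=True)
class DescriptorPanel:
    """Raw descriptor values for one molecule."""

    mw: float
    logp: float
    hbd: int
    hba: int
    qed: float
    syn_score: float = math.nan


@dataclass(frozen=True)
class ScoreCard:
    """Normalized scores, composite rank and filter verdicts."""

    qed_norm: float
    syn_norm: float
    my_score: float
    passed_qed: bool
    passed_ro5: bool
    passed_syn: bool


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {smiles!r}")
    return mol


def compute_panel(smiles: str,
                  table: "FragmentTable | None" = None) -> DescriptorPanel:
    """Descriptor panel from the RDKit descriptor engine.

    HBD/HBA follow the Lipinski N+O convention (NHOH / NO counts).  The
    synthesizability score is filled in when a fragment table is supplied.
    """
    mol = _mol(smiles)
    syn = table.score_mol(mol) if table is not None else math.nan
    return DescriptorPanel(
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        hbd=Lipinski.NHOHCount(mol),
        hba=Lipinski.NOCount(mol),
        qed=QED.qed(mol),
        syn_score=syn,
    )


def ro5_pass(panel: DescriptorPanel, allowed_violations: int = 0) -> bool:
    """Lipinski rule of 5 with <= semantics at every boundary."""
    violations = sum([panel.mw > 500.0, panel.logp > 5.0,
                      panel.hbd > 5, panel.hba > 10])
    return violations <= allowed_violations


# ---------------------------------------------------------------------------
# Bernoulli fragment synthesizability score

class FragmentTable:
    """Log-likelihood-ratio contributions of circular fragments.

    Trained from an easy-to-synthesize and a hard-to-synthesize molecule
    set: each fragment f scores
    ``ln[(n_easy(f)+p)/(N_easy+2p)] - ln[(n_hard(f)+p)/(N_hard+2p)]``
    with pseudocount p.  Fragments unseen in training contribute the
    smoothed unseen value, never an error.  A molecule's score is the sum
    over its *distinct* fragments.
    """

    def __init__(self, values: Mapping[int, float], unseen_value: float,
                 radius: int = 2, pseudocount: float = 1.0) -> None:
        self.values = dict(values)
        self.unseen_value = float(unseen_value)
        self.radius = radius
        self.pseudocount = pseudocount
        if not all(math.isfinite(v) for v in self.values.values()):
            raise ValueError("fragment values must be finite")

    # -- fragments ----------------------------------------------------------

    @staticmethod
    def fragments_of(mol: Chem.Mol, radius: int) -> set[int]:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
        fp = gen.GetSparseCountFingerprint(mol)
        return set(fp.GetNonzeroElements().keys())

    # -- training -----------------------------------------------------------

    @classmethod
    def train(cls, easy: Sequence[str], hard: Sequence[str],
              pseudocount: float = 1.0, radius: int = 2) -> "FragmentTable":
        if not easy or not hard:
            raise ValueError("both training sets must be non-empty")
        n_easy: dict[int, int] = {}
        n_hard: dict[int, int] = {}
        for smiles_set, counts in ((easy, n_easy), (hard, n_hard)):
            for s in smiles_set:
                for f in cls.fragments_of(_mol(s), radius):
                    counts[f] = counts.get(f, 0) + 1
        N_e, N_h, p = len(easy), len(hard), pseudocount

        def llr(ne: int, nh: int) -> float:
            return (math.log((ne + p) / (N_e + 2 * p))
                    - math.log((nh + p) / (N_h + 2 * p)))

        values = {f: llr(n_easy.get(f, 0), n_hard.get(f, 0))
                  for f in set(n_easy) | set(n_hard)}
        return cls(values, unseen_value=llr(0, 0), radius=radius,
                   pseudocount=pseudocount)

    # -- scoring ------------------------------------------------------------

    def score_mol(self, mol: Chem.Mol) -> float:
        frags = self.fragments_of(mol, self.radius)
        return sum(self.values.get(f, self.unseen_value) for f in frags)

    def score(self, smiles: str) -> float:
        return self.score_mol(_mol(smiles))

    # -- serialization (two-column CSV + JSON header) -----------------------

    def save(self, csv_path: str | Path, header_path: str | Path) -> None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fragment_id", "value"])
            for f in sorted(self.values):
                writer.writerow([f, repr(self.values[f])])
        Path(header_path).write_text(json.dumps(
            {"radius": self.radius, "pseudocount": self.pseudocount,
             "unseen_value": self.unseen_value}, indent=2) + "\n")

    @classmethod
    def load(cls, csv_path: str | Path,
             header_path: str | Path) -> "FragmentTable":
        header = json.loads(Path(header_path).read_text())
        values: dict[int, float] = {}
        with open(csv_path, newline="") as fh:
            for row in csv.DictReader(fh):
                values[int(row["fragment_id"])] = float(row["value"])
        return cls(values, unseen_value=header["unseen_value"],
                   radius=header["radius"],
                   pseudocount=header["pseudocount"])


def syn_score(smiles: str, table: FragmentTable) -> float:
    """Synthesizability score of a molecule under a trained table."""
    return table.score(smiles)


def train_fragment_table(easy: Sequence[str], hard: Sequence[str],
                         pseudocount: float = 1.0,
                         radius: int = 2) -> FragmentTable:
    return FragmentTable.train(easy, hard, pseudocount, radius)


# ---------------------------------------------------------------------------
# normalization, composite score, cascade

def _minmax(value: float, lo: float, hi: float) -> float:
    return (value - lo) / (hi - lo)


def normalize_and_rank(panels: Mapping[str, DescriptorPanel],
                       reference: Sequence[DescriptorPanel] | None = None,
                       allowed_violations: int = 0,
                       ) -> list[tuple[str, ScoreCard]]:
    """Min-max normalize QED and syn scores and rank by "My score".

    ``reference`` is the set the min/max are taken over (default: the
    candidates themselves).  Output is sorted descending by my_score.
    A single candidate with no reference normalizes to 0 by convention;
    constant reference values otherwise raise ValueError.
    """
    ref = list(reference) if reference is not None else list(panels.values())
    if not ref:
        raise ValueError("empty reference set")
    qed_lo, qed_hi = min(p.qed for p in ref), max(p.qed for p in ref)
    syn_lo = min(p.syn_score for p in ref)
    syn_hi = max(p.syn_score for p in ref)
    degenerate_qed = math.isclose(qed_lo, qed_hi)
    degenerate_syn = math.isclose(syn_lo, syn_hi)
    if (degenerate_qed or degenerate_syn) and len(panels) > 1:
        raise ValueError("constant reference values: normalization is "
                         "degenerate for more than one candidate")

    out = []
    for key, panel in panels.items():
        qn = 0.0 if degenerate_qed else _minmax(panel.qed, qed_lo, qed_hi)
        sn = 0.0 if degenerate_syn else _minmax(panel.syn_score, syn_lo,
                                                syn_hi)
        card = ScoreCard(
            qed_norm=qn, syn_norm=sn,
            my_score=100.0 * (qn + sn) / 2.0,
            passed_qed=panel.qed >= QED_THRESHOLD,
            passed_ro5=ro5_pass(panel, allowed_violations),
            passed_syn=panel.syn_score >= SYN_THRESHOLD,
        )
        out.append((key, card))
    out.sort(key=lambda kv: kv[1].my_score, reverse=True)
    return out


@dataclass(frozen=True)
class CascadeReport:
    """Independent per-stage counts plus the conjunction."""

    n_input: int
    n_pass_qed: int
    n_pass_ro5: int
    n_pass_syn: int
    n_pass_qed_ro5: int
    n_pass_all: int

    @staticmethod
    def percent(passed: int, of: int) -> float:
        """Pass rate in percent, reported to two decimals."""
        return round(100.0 * passed / of, 2)

    @property
    def qed_ro5_rate(self) -> float:
        return self.percent(self.n_pass_qed_ro5, self.n_input)

    def to_dict(self) -> dict[str, float]:
        return {"input": self.n_input, "pass_qed": self.n_pass_qed,
                "pass_ro5": self.n_pass_ro5, "pass_syn": self.n_pass_syn,
                "pass_qed_ro5": self.n_pass_qed_ro5,
                "pass_all": self.n_pass_all,
                "qed_ro5_rate_percent": self.qed_ro5_rate}


def filter_cascade(panels: Mapping[str, DescriptorPanel],
                   allowed_violations: int = 0,
                   ) -> tuple[list[str], CascadeReport]:
    """Apply the three discriminators; returns survivor keys + counts.

    The filters are independent predicates, so the surviving set does not
    depend on stage order; thresholds: QED >= 0.5, rule-of-5 pass, and
    synthesizability score >= 0 (exactly 0 is retained).
    """
    qed_ok = {k for k, p in panels.items() if p.qed >= QED_THRESHOLD}
    ro5_ok = {k for k, p in panels.items()
              if ro5_pass(p, allowed_violations)}
    syn_ok = {k for k, p in panels.items()
              if p.syn_score >= SYN_THRESHOLD}
    both = qed_ok & ro5_ok
    survivors = [k for k in panels if k in both and k in syn_ok]
    report = CascadeReport(
        n_input=len(panels), n_pass_qed=len(qed_ok),
        n_pass_ro5=len(ro5_ok), n_pass_syn=len(syn_ok),
        n_pass_qed_ro5=len(both), n_pass_all=len(survivors))
    return survivors, report
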