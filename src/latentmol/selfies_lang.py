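"""A restricted SELFIES-style molecular string grammar.

SELFIES (Self-Referencing Embedded Strings) is a molecular notation in which
*every* syntactically well-formed token string decodes to a chemically valid
molecule.  That robustness is what makes the notation safe to hand to a
generative sequence model: decoded predictions can never be syntactically
broken the way sampled SMILES can.

This module implements the grammar for the neutral organic subset the
pipeline works with:

* atom tokens ``[C] [=C] [#C] [N] [=N] [#N] [O] [=O] [S] [=S] [P] [B]
  [F] [Cl] [Br] [I] [Se] [Sn]`` — an optional bond prefix (``=`` double,
  ``#`` triple) states the bond to the previous chain atom;
* branch tokens ``[Branch1] [=Branch1] [#Branch1] [Branch2] ...`` — the
  following index token(s) give the branch length in tokens;
* ring tokens ``[Ring1] [Ring2] [=Ring1] [=Ring2] [#Ring1]`` — the following
  index token(s) give how far back along the derivation order the ring bond
  reaches.

Decoding is a valence-constrained derivation: bond orders are capped by the
remaining valence of both endpoints, and tokens that cannot apply at the
current derivation state are skipped.  Those two rules are what guarantee a
valid molecule for arbitrary token streams.

Encoding (SMILES -> tokens) walks a kekulized RDKit molecule depth-first,
emitting branch blocks for non-final children and ring-closure tokens at the
later-visited endpoint of each ring bond.  Stereochemistry is always dropped
(generic SMILES); charged, isotopic or radical species are outside the
grammar and raise :class:`~latentmol.errors.EncodeError`.
"""

from __future__ import annotations

import itertools
import re
from typing import Iterator, Sequence

from rdkit import Chem, RDLogger

from .errors import DecodeError, EncodeError, ParseError

RDLogger.DisableLog("rdApp.*")

# Maximum total bond order (implicit hydrogens fill the remainder).
MAX_VALENCE = {
    "H": 1, "F": 1, "Cl": 1, "Br": 1, "I": 1,
    "O": 2, "N": 3, "B": 3, "C": 4, "Sn": 4, "P": 5, "S": 6, "Se": 6,
}

_BOND_PREFIX = {"": 1, "=": 2, "#": 3}
_PREFIX_OF_ORDER = {1: "", 2: "=", 3: "#"}

# Index alphabet: the overloaded meaning of tokens when they follow a
# Branch/Ring token.  Sixteen entries encode 0..15; two consecutive index
# tokens encode 16*q1 + q2 (0..255).
INDEX_ALPHABET = (
    "[C]", "[Ring1]", "[Ring2]", "[Branch1]", "[=Branch1]", "[#Branch1]",
    "[Branch2]", "[=Branch2]", "[#Branch2]", "[O]", "[N]", "[=N]", "[=C]",
    "[#C]", "[S]", "[P]",
)
_INDEX_OF = {tok: i for i, tok in enumerate(INDEX_ALPHABET)}

_TOKEN_RE = re.compile(r"\[[^\[\]]*\]")
_ATOM_RE = re.compile(r"\[(=|#)?([A-Z][a-z]?)\]")
_BRANCH_RE = re.compile(r"\[(=|#)?Branch([12])\]")
_RING_RE = re.compile(r"\[(=|#)?Ring([12])\]")


def tokenize(selfies: str) -> list[str]:
    """Split a SELFIES string into its bracketed tokens.

    Raises :class:`DecodeError` if any character falls outside a bracket
    pair.
    """
    tokens = _TOKEN_RE.findall(selfies)
    if "".join(tokens) != selfies:
        raise DecodeError(f"malformed SELFIES string: {selfies!r}")
    return tokens


def token_length(selfies: str) -> int:
    """Number of bracketed tokens in a SELFIES string."""
    return len(tokenize(selfies))


def _token_index_value(token: str) -> int:
    # Unlisted tokens read as index 0, so any token stream stays decodable.
    return _INDEX_OF.get(token, 0)


class _Graph:
    """Mutable molecular graph built during derivation."""

    def __init__(self) -> None:
        self.elements: list[str] = []
        self.used: list[int] = []        # bond order already consumed
        self.bonds: dict[tuple[int, int], int] = {}

    def free(self, i: int) -> int:
        return MAX_VALENCE[self.elements[i]] - self.used[i]

    def add_atom(self, element: str) -> int:
        self.elements.append(element)
        self.used.append(0)
        return len(self.elements) - 1

    def add_bond(self, i: int, j: int, order: int) -> None:
        key = (min(i, j), max(i, j))
        self.bonds[key] = order
        self.used[i] += order
        self.used[j] += order

    def has_bond(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.bonds

    def to_mol(self) -> Chem.Mol:
        mol = Chem.RWMol()
        for el in self.elements:
            mol.AddAtom(Chem.Atom(el))
        order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                     3: Chem.BondType.TRIPLE}
        for (i, j), order in self.bonds.items():
            mol.AddBond(i, j, order_map[order])
        out = mol.GetMol()
        Chem.SanitizeMol(out)
        return out


def _derive(stream: Iterator[str], graph: _Graph, attach: int | None,
            attach_order: int | None) -> None:
    """Consume ``stream``, growing ``graph`` from atom ``attach``.

    ``attach_order`` overrides the bond prefix of the first atom token (used
    when entering a branch, whose Branch token carries the bond order).
    """
    current = attach
    first = attach_order is not None
    for token in stream:
        m = _ATOM_RE.fullmatch(token)
        if m is not None:
            prefix, element = m.groups()
            if element not in MAX_VALENCE or element == "H":
                raise DecodeError(f"unknown atom token {token!r}")
            if current is None:
                current = graph.add_atom(element)
                continue
            if graph.free(current) == 0:
                break  # saturated chain atom terminates the derivation
            order = attach_order if first else _BOND_PREFIX[prefix or ""]
            first = False
            order = min(order, graph.free(current), MAX_VALENCE[element])
            new = graph.add_atom(element)
            graph.add_bond(current, new, order)
            current = new
            continue

        m = _BRANCH_RE.fullmatch(token)
        if m is not None:
            prefix, size = m.groups()
            q = _read_index(stream, int(size))
            if q is None:
                break
            body = _take(stream, q + 1)
            if current is None or graph.free(current) < 1:
                continue  # branch cannot apply here; body is skipped
            order = min(_BOND_PREFIX[prefix or ""], graph.free(current))
            _derive(iter(body), graph, current, order)
            continue

        m = _RING_RE.fullmatch(token)
        if m is not None:
            prefix, size = m.groups()
            q = _read_index(stream, int(size))
            if q is None:
                break
            if current is None:
                continue
            target = max(0, current - (q + 1))
            if target == current or graph.has_bond(current, target):
                continue
            order = min(_BOND_PREFIX[prefix or ""], graph.free(current),
                        graph.free(target))
            if order >= 1:
                graph.add_bond(current, target, order)
            continue

        raise DecodeError(f"unrecognized token {token!r}")


def _read_index(stream: Iterator[str], n_tokens: int) -> int | None:
    value = 0
    for _ in range(n_tokens):
        tok = next(stream, None)
        if tok is None:
            return None
        value = value * 16 + _token_index_value(tok)
    return value


def _take(stream: Iterator[str], n: int) -> list[str]:
    return list(itertools.islice(stream, n))


def decode(selfies: str) -> str:
    """Decode a SELFIES string to a canonical generic SMILES.

    Any well-formed token stream decodes without error; tokens that cannot
    apply at the current derivation state are skipped.  An empty derivation
    returns the empty string.
    """
    tokens = tokenize(selfies)
    graph = _Graph()
    _derive(iter(tokens), graph, None, None)
    if not graph.elements:
        return ""
    return Chem.MolToSmiles(graph.to_mol())


# ---------------------------------------------------------------------------
# Encoding

def canonicalize_generic(smiles: str) -> str:
    """Canonical stereochemistry-free ("generic") SMILES.

    Idempotent; stereocenter and double-bond-geometry annotations are
    removed before canonicalization.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def _prepared_mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in MAX_VALENCE or atom.GetSymbol() == "H":
            raise EncodeError(
                f"element {atom.GetSymbol()} outside the grammar: {smiles!r}")
        if atom.GetFormalCharge() or atom.GetIsotope() \
                or atom.GetNumRadicalElectrons():
            raise EncodeError(
                f"charged/isotopic/radical species unsupported: {smiles!r}")
    return mol


def encode(smiles: str) -> str:
    """Translate a SMILES string into the restricted SELFIES grammar.

    Round trip guarantee: ``decode(encode(s))`` equals
    ``canonicalize_generic(s)``.
    """
    mol = _prepared_mol(smiles)
    if mol.GetNumAtoms() == 0:
        return ""
    frags = Chem.GetMolFrags(mol)
    if len(frags) > 1:
        raise EncodeError(f"multi-fragment species unsupported: {smiles!r}")

    # One DFS fixes both the spanning tree (children_of, in visit order) and
    # the back edges (ring bonds); the emitter below replays exactly it, so
    # decoder derivation order equals DFS pre-order.
    children_of: dict[int, list[int]] = {}
    back_edges: set[frozenset[int]] = set()
    seen = {0}

    def classify(i: int, parent: int) -> None:
        children_of[i] = []
        for nb in mol.GetAtomWithIdx(i).GetNeighbors():
            j = nb.GetIdx()
            if j == parent:
                continue
            if j in seen:
                # tree edges are skipped via the parent check, so any
                # already-seen neighbor marks a ring bond
                back_edges.add(frozenset((i, j)))
            else:
                seen.add(j)
                children_of[i].append(j)
                classify(j, i)

    classify(0, -1)

    order_of: dict[int, int] = {}       # rdkit atom idx -> derivation position
    counter = [0]

    def emit(atom_idx: int, parent: int | None) -> list[str]:
        order_of[atom_idx] = counter[0]
        counter[0] += 1
        atom = mol.GetAtomWithIdx(atom_idx)
        if parent is None:
            prefix = ""
        else:
            bond = mol.GetBondBetweenAtoms(parent, atom_idx)
            prefix = _PREFIX_OF_ORDER[int(bond.GetBondTypeAsDouble())]
        tokens = [f"[{prefix}{atom.GetSymbol()}]"]

        # ring closures terminating at this atom (partner already emitted)
        for nb in atom.GetNeighbors():
            j = nb.GetIdx()
            if frozenset((atom_idx, j)) in back_edges and j in order_of:
                bond = mol.GetBondBetweenAtoms(atom_idx, j)
                bprefix = _PREFIX_OF_ORDER[int(bond.GetBondTypeAsDouble())]
                q = order_of[atom_idx] - order_of[j] - 1
                tokens.extend(_ring_tokens(bprefix, q))

        children = children_of[atom_idx]
        for pos, j in enumerate(children):
            bond = mol.GetBondBetweenAtoms(atom_idx, j)
            border = int(bond.GetBondTypeAsDouble())
            if pos < len(children) - 1:
                body = emit(j, atom_idx)
                body[0] = _strip_prefix(body[0])
                tokens.extend(
                    _branch_tokens(_PREFIX_OF_ORDER[border], len(body)))
                tokens.extend(body)
            else:
                tokens.extend(emit(j, atom_idx))
        return tokens

    tokens = emit(0, None)
    return "".join(tokens)


def _strip_prefix(atom_token: str) -> str:
    m = _ATOM_RE.fullmatch(atom_token)
    return f"[{m.group(2)}]"


def _branch_tokens(prefix: str, body_len: int) -> list[str]:
    q = body_len - 1
    if q < 16:
        return [f"[{prefix}Branch1]", INDEX_ALPHABET[q]]
    if q < 256:
        return [f"[{prefix}Branch2]", INDEX_ALPHABET[q // 16],
                INDEX_ALPHABET[q % 16]]
    raise EncodeError("branch longer than 256 tokens")


def _ring_tokens(prefix: str, q: int) -> list[str]:
    if q < 16:
        return [f"[{prefix}Ring1]", INDEX_ALPHABET[q]]
    if q < 256:
        return [f"[{prefix}Ring2]", INDEX_ALPHABET[q // 16],
                INDEX_ALPHABET[q % 16]]
    raise EncodeError("ring span longer than 256 atoms")


def smiles_to_selfies(smiles: str) -> str:
    """Alias of :func:`encode` under the pipeline's vocabulary."""
    return encode(smiles)


def selfies_to_smiles(selfies: str) -> str:
    """Alias of :func:`decode`; returns canonical generic SMILES."""
    return decode(selfies)


def alphabet_of(corpus: Sequence[str]) -> set[str]:
    """Distinct tokens appearing in a corpus of SELFIES strings."""
    tokens: set[str] = set()
    for s in corpus:
        tokens.update(tokenize(s))
    return tokens
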