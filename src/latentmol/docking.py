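"""Batch docking orchestration with pluggable backends.

Candidates are embedded in 3D (ETKDG + MMFF-free distance geometry with
hydrogens), written to ligand files, and docked against every receptor in
a grid of ligand x receptor pairs.  Two backends exist:

* ``mock`` — a deterministic pseudo-energy from a hash of (canonical
  SMILES, receptor id), mapped into [-12, -4] kcal/mol.  It makes the full
  pipeline runnable and testable with no external binary.
* ``vina`` — drives the AutoDock Vina executable and parses the best-pose
  affinity from its output table.

Per-ligand average binding energies over the receptor set rank the
candidates (most negative mean first).  A utility quantifies why docking
search is never systematic: the conformation count of a brute-force grid
walk and the years it would take to enumerate.
"""

from __future__ import annotations

import csv
import hashlib
import math
import re
import shutil
import subprocess
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import BackendError, ParseError
from .selfies_lang import canonicalize_generic

SECONDS_PER_YEAR = 365 * 24 * 3600
MOCK_ENERGY_RANGE = (-12.0, -4.0)


@dataclass(frozen=True)
class ReceptorSpec:
    """A prepared receptor (PDBQT) plus its docking box in Angstroms."""

    id: str
    file: str = ""
    box_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    box_size: tuple[float, float, float] = (20.0, 20.0, 20.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.box_size):
            raise ValueError("box_size components must be positive")


@dataclass(frozen=True)
class DockingResult:
    """Best-pose binding energy for one ligand x receptor pair."""

    ligand_id: str
    receptor_id: str
    energy: float               # kcal/mol; more negative binds stronger
    pose_file: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.energy):
            raise ValueError("energy must be finite")


# ---------------------------------------------------------------------------
# 3D embedding

def embed_3d(smiles: str, out_path: str | Path, seed: int = 42) -> Path:
    """Write an all-atom 3D SDF for a molecule (deterministic per seed).

    Raises :class:`BackendError` when distance-geometry embedding fails
    (e.g. pathological macrocycles); callers record such molecules in a
    skip report.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise BackendError(f"3D embedding failed for {smiles!r}")
    AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
    out_path = Path(out_path)
    with Chem.SDWriter(str(out_path)) as writer:
        writer.write(mol)
    return out_path


def embed_all(smiles_by_id: dict[str, str], out_dir: str | Path,
              seed: int = 42) -> tuple[dict[str, Path], dict[str, str]]:
    """Embed every ligand; returns (files, skip report of id -> reason)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    skipped: dict[str, str] = {}
    for lig_id, smiles in smiles_by_id.items():
        try:
            files[lig_id] = embed_3d(smiles, out_dir / f"{lig_id}.sdf", seed)
        except (BackendError, ParseError) as exc:
            skipped[lig_id] = str(exc)
    return files, skipped


# ---------------------------------------------------------------------------
# backends

def mock_energy(smiles: str, receptor_id: str) -> float:
    """Deterministic pseudo-energy in [-12, -4] kcal/mol from a hash."""
    key = f"{canonicalize_generic(smiles)}|{receptor_id}".encode()
    digest = hashlib.sha256(key).digest()
    frac = int.from_bytes(digest[:8], "big") / 2 ** 64
    lo, hi = MOCK_ENERGY_RANGE
    return lo + frac * (hi - lo)


_VINA_TABLE_RE = re.compile(r"^\s*1\s+(-?\d+(?:\.\d+)?)", re.MULTILINE)


def parse_vina_output(text: str) -> float:
    """Best-pose affinity (mode 1) from an AutoDock Vina results table."""
    m = _VINA_TABLE_RE.search(text)
    if m is None:
        raise BackendError("no affinity table in Vina output")
    return float(m.group(1))


def dock(smiles: str, ligand_id: str, receptor: ReceptorSpec,
         backend: str = "mock", ligand_file: str | Path | None = None,
         vina_exe: str = "vina") -> DockingResult:
    """Dock one ligand against one receptor with the chosen backend."""
    if backend == "mock":
        return DockingResult(ligand_id=ligand_id, receptor_id=receptor.id,
                             energy=mock_energy(smiles, receptor.id))
    if backend == "vina":
        if shutil.which(vina_exe) is None:
            raise BackendError(
                f"AutoDock Vina executable {vina_exe!r} not found on PATH; "
                "install it or use backend='mock'")
        if ligand_file is None:
            raise BackendError("vina backend requires a prepared ligand file")
        cx, cy, cz = receptor.box_center
        sx, sy, sz = receptor.box_size
        cmd = [vina_exe, "--receptor", receptor.file,
               "--ligand", str(ligand_file),
               "--center_x", str(cx), "--center_y", str(cy),
               "--center_z", str(cz), "--size_x", str(sx),
               "--size_y", str(sy), "--size_z", str(sz)]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise BackendError(
                f"vina failed for {ligand_id} x {receptor.id}:\n{proc.stderr}")
        return DockingResult(ligand_id=ligand_id, receptor_id=receptor.id,
                             energy=parse_vina_output(proc.stdout))
    raise BackendError(f"unknown backend {backend!r}")


def dock_grid(smiles_by_id: dict[str, str],
              receptors: Sequence[ReceptorSpec],
              backend: str = "mock") -> list[DockingResult]:
    """Dock every ligand against every receptor; failures are warned and
    recorded as missing pairs."""
    results = []
    for lig_id, smiles in smiles_by_id.items():
        for receptor in receptors:
            try:
                results.append(dock(smiles, lig_id, receptor, backend))
            except BackendError as exc:
                warnings.warn(f"docking failed for {lig_id} x "
                              f"{receptor.id}: {exc}", stacklevel=2)
    return results


# ---------------------------------------------------------------------------
# aggregation

def average_binding(results: Sequence[DockingResult]) -> dict[str, float]:
    """Arithmetic mean energy per ligand over its receptors."""
    if not results:
        raise ValueError("empty result set")
    sums: dict[str, list[float]] = {}
    for r in results:
        sums.setdefault(r.ligand_id, []).append(r.energy)
    # fsum is exactly rounded, so the mean is receptor-order invariant
    return {lig: math.fsum(es) / len(es) for lig, es in sums.items()}


def rank_ligands(results: Sequence[DockingResult]
                 ) -> list[tuple[str, float]]:
    """Ligands ordered ascending by mean energy (most negative first);
    ties break on ligand id so the ranking is input-order invariant."""
    means = average_binding(results)
    return sorted(means.items(), key=lambda kv: (kv[1], kv[0]))


def minimum_per_receptor(results: Sequence[DockingResult]
                         ) -> dict[str, tuple[str, float]]:
    """Strongest (most negative) energy and its ligand per receptor."""
    best: dict[str, tuple[str, float]] = {}
    for r in results:
        if r.receptor_id not in best or r.energy < best[r.receptor_id][1]:
            best[r.receptor_id] = (r.ligand_id, r.energy)
    return best


def write_results_csv(path: str | Path,
                      results: Sequence[DockingResult]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ligand_id", "receptor_id", "energy_kcal_mol"])
        for r in results:
            writer.writerow([r.ligand_id, r.receptor_id, f"{r.energy:.1f}"])


def write_ranking_csv(path: str | Path,
                      results: Sequence[DockingResult]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ligand_id", "mean_energy_kcal_mol"])
        for lig, mean in rank_ligands(results):
            writer.writerow([lig, f"{mean:.2f}"])


# ---------------------------------------------------------------------------
# systematic-search combinatorics

def systematic_search_size(box_volume: float, grid_step: float,
                           angle_step: float, n_torsions: int) -> float:
    """Conformation count of a brute-force systematic search.

    A cubic box of ``box_volume`` is walked on a ``grid_step`` lattice;
    three rigid-body rotations and each torsion are swept at
    ``angle_step``.  Non-divisible angle steps round to the nearest
    integer step count with a warning.
    """
    if box_volume <= 0 or grid_step <= 0 or angle_step <= 0 or n_torsions < 0:
        raise ValueError("inputs must be positive (torsions non-negative)")
    n_angle = 360.0 / angle_step
    if abs(n_angle - round(n_angle)) > 1e-9:
        warnings.warn(f"angle step {angle_step} does not divide 360 degrees; "
                      "using the nearest integer step count", stacklevel=2)
        n_angle = round(n_angle)
    n_grid = box_volume ** (1.0 / 3.0) / grid_step
    return n_grid ** 3 * n_angle ** (3 + n_torsions)


def round_to_sig_figs(value: float, n_sig: int = 1) -> float:
    """Round to ``n_sig`` significant figures (reporting convention)."""
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    factor = 10.0 ** (exponent - n_sig + 1)
    return round(value / factor) * factor


def enumeration_time(count: float, rate_per_second: float) -> int:
    """Whole years (truncated) to enumerate ``count`` conformations."""
    if count <= 0 or rate_per_second <= 0:
        raise ValueError("count and rate must be positive")
    return int(count / rate_per_second / SECONDS_PER_YEAR)
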