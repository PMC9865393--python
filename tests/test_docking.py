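"""Docking orchestration: mock backend, 3D embedding, ranking, search math."""

import csv

import numpy as np
import pytest
from rdkit import Chem

from latentmol import DockingResult, ReceptorSpec, average_binding, dock, \
    embed_3d, enumeration_time, mock_energy, rank_ligands, \
    systematic_search_size
from latentmol.docking import (MOCK_ENERGY_RANGE, embed_all,
                               minimum_per_receptor, parse_vina_output,
                               round_to_sig_figs, write_results_csv)
from latentmol.errors import BackendError

# Screening energies (kcal/mol) of 16 candidates against the three
# receptor domains, used as printed input data for the aggregation ops.
SCREEN_ENERGIES = {
    4: (-7.9, -8.2, -8.6), 5: (-6.5, -6.9, -6.7), 6: (-8.6, -8.1, -8.7),
    7: (-9.2, -10.0, -8.7), 8: (-8.8, -9.0, -9.2), 9: (-8.0, -8.2, -8.5),
    10: (-10.0, -9.1, -9.2), 11: (-8.7, -8.8, -10.0),
    12: (-9.9, -9.5, -10.0), 14: (-6.6, -6.9, -7.2),
    15: (-7.0, -7.1, -7.3), 16: (-7.5, -7.4, -7.7), 17: (-7.0, -7.1, -7.3),
    18: (-9.7, -8.1, -8.3), 19: (-8.8, -10.0, -10.0),
    20: (-9.5, -10.0, -9.6),
}
RECEPTORS = ("7NPC", "7NP5", "7KXD")


def screen_results():
    return [DockingResult(f"mol{m}", r, e)
            for m, energies in SCREEN_ENERGIES.items()
            for r, e in zip(RECEPTORS, energies)]


# -- mock backend -----------------------------------------------------------

def test_mock_energy_deterministic_and_in_range():
    first = mock_energy("CCO", "7NPC")
    assert first == mock_energy("CCO", "7NPC")
    lo, hi = MOCK_ENERGY_RANGE
    for smiles in ("CCO", "c1ccccc1", "CC(N)C(=O)O"):
        for receptor in RECEPTORS:
            assert lo <= mock_energy(smiles, receptor) <= hi


def test_mock_energy_keyed_on_canonical_form():
    assert mock_energy("OCC", "7NPC") == mock_energy("CCO", "7NPC")
    assert mock_energy("CCO", "7NPC") != mock_energy("CCO", "7NP5")


def test_dock_mock_backend_contract():
    receptor = ReceptorSpec(id="7NPC")
    result = dock("CCO", "lig1", receptor, backend="mock")
    assert result.ligand_id == "lig1" and result.receptor_id == "7NPC"
    assert result.energy == mock_energy("CCO", "7NPC")


def test_unknown_and_missing_backends_rejected():
    receptor = ReceptorSpec(id="r")
    with pytest.raises(BackendError):
        dock("CCO", "l", receptor, backend="nope")
    with pytest.raises(BackendError, match="not found"):
        dock("CCO", "l", receptor, backend="vina",
             vina_exe="definitely-not-vina-xyz")


def test_parse_vina_output_best_pose():
    log = """\
mode |   affinity | dist from best mode
     | (kcal/mol) | rmsd l.b.| rmsd u.b.
-----+------------+----------+----------
   1       -7.3          0.000      0.000
   2       -7.1          1.922      2.934
"""
    assert parse_vina_output(log) == -7.3
    with pytest.raises(BackendError):
        parse_vina_output("garbage with no table")


# -- 3D embedding -----------------------------------------------------------

def test_ethane_embedding_geometry(tmp_path):
    path = embed_3d("CC", tmp_path / "ethane.sdf", seed=42)
    mol = next(Chem.SDMolSupplier(str(path), removeHs=False))
    assert mol.GetNumAtoms() == 8   # 2 C + 6 H
    conf = mol.GetConformer()
    d = np.linalg.norm(np.array(conf.GetAtomPosition(0))
                       - np.array(conf.GetAtomPosition(1)))
    assert d == pytest.approx(1.54, abs=0.05)


def test_embedding_deterministic_under_seed(tmp_path):
    p1 = embed_3d("CCO", tmp_path / "a.sdf", seed=7)
    p2 = embed_3d("CCO", tmp_path / "b.sdf", seed=7)
    m1 = next(Chem.SDMolSupplier(str(p1), removeHs=False))
    m2 = next(Chem.SDMolSupplier(str(p2), removeHs=False))
    c1 = m1.GetConformer().GetPositions()
    c2 = m2.GetConformer().GetPositions()
    assert np.allclose(c1, c2)


def test_failing_molecules_land_in_skip_report(tmp_path):
    files, skipped = embed_all(
        {"good": "CCO", "bad": "this_is_not_smiles"}, tmp_path)
    assert "good" in files and "bad" not in files
    assert "bad" in skipped


# -- aggregation ------------------------------------------------------------

def test_screening_means_and_extremes():
    """Means over the three receptors: best -9.80, worst -6.70."""
    results = screen_results()
    means = average_binding(results)
    assert means["mol12"] == pytest.approx(-9.80, abs=0.005)
    assert means["mol5"] == pytest.approx(-6.70, abs=0.005)
    ranking = rank_ligands(results)
    assert ranking[0][0] == "mol12"
    assert ranking[-1][0] == "mol5"


def test_per_receptor_minimum():
    best = minimum_per_receptor(screen_results())
    assert best["7NPC"] == ("mol10", -10.0)
    assert best["7NP5"][1] == -10.0 and best["7KXD"][1] == -10.0


def test_ranking_invariant_to_receptor_order():
    results = screen_results()
    shuffled = list(reversed(results))
    assert rank_ligands(results) == rank_ligands(shuffled)


def test_single_receptor_mean_is_the_energy():
    res = [DockingResult("l", "r", -8.1)]
    assert average_binding(res) == {"l": -8.1}
    with pytest.raises(ValueError):
        average_binding([])


def test_emitted_csv_reproduces_the_means(tmp_path):
    results = screen_results()
    path = tmp_path / "pairs.csv"
    write_results_csv(path, results)
    by_ligand = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            by_ligand.setdefault(row["ligand_id"], []).append(
                float(row["energy_kcal_mol"]))
    means = average_binding(results)
    for ligand, energies in by_ligand.items():
        assert sum(energies) / len(energies) \
            == pytest.approx(means[ligand], abs=1e-9)


# -- systematic-search combinatorics ---------------------------------------

def test_systematic_search_count_and_years():
    count = systematic_search_size(1000.0, 0.5, 10.0, 4)
    assert round_to_sig_figs(count, 1) == 6e14
    assert enumeration_time(round_to_sig_figs(count, 1), 1000.0) == 19025


def test_degenerate_grid_is_single_conformation():
    assert systematic_search_size(1.0, 1.0, 360.0, 0) == pytest.approx(1.0)


def test_non_divisible_angle_step_warns():
    with pytest.warns(UserWarning, match="angle step"):
        systematic_search_size(1000.0, 0.5, 7.0, 1)


def test_receptor_box_must_be_positive():
    with pytest.raises(ValueError):
        ReceptorSpec(id="r", box_size=(0.0, 10.0, 10.0))
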