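"""Discriminators, synthesizability table, normalization and cascade."""

import itertools
import math

import pytest

from latentmol import CascadeReport, DescriptorPanel, FragmentTable, \
    compute_panel, filter_cascade, normalize_and_rank, ro5_pass
from latentmol.fixtures import make_easy_hard_sets


def panel(qed=0.7, syn=10.0, mw=300.0, logp=2.0, hbd=1, hba=4):
    return DescriptorPanel(mw=mw, logp=logp, hbd=hbd, hba=hba,
                           qed=qed, syn_score=syn)


# -- descriptor panel -------------------------------------------------------

def test_ethanol_panel_matches_hand_computation():
    """MW from atomic masses; one OH donor; one N+O acceptor."""
    p = compute_panel("CCO")
    assert p.mw == pytest.approx(46.07, abs=0.01)
    assert p.hbd == 1 and p.hba == 1
    assert 0.0 <= p.qed <= 1.0


@pytest.mark.parametrize("smiles", ["CCO", "c1ccccc1", "CC(=O)Oc1ccccc1C(=O)O"])
def test_qed_always_in_unit_interval(smiles):
    assert 0.0 <= compute_panel(smiles).qed <= 1.0


# -- rule of 5 --------------------------------------------------------------

@pytest.mark.parametrize("kwargs,expected", [
    (dict(mw=600.0), False),                      # single breach fails
    (dict(mw=180.0, logp=1.2, hbd=1, hba=4), True),
    (dict(mw=500.0), True),                       # boundary: <= semantics
    (dict(logp=5.0, hbd=5, hba=10), True),
])
def test_ro5_strict_boundaries(kwargs, expected):
    assert ro5_pass(panel(**kwargs)) is expected


def test_ro5_violation_allowance():
    breached = panel(mw=600.0)
    assert not ro5_pass(breached)
    assert ro5_pass(breached, allowed_violations=1)


# -- synthesizability fragment table ---------------------------------------

def test_score_is_sum_over_distinct_fragments():
    from rdkit import Chem
    mol = Chem.MolFromSmiles("CCO")
    frags = sorted(FragmentTable.fragments_of(mol, radius=2))
    values = {frags[0]: 2.0, frags[1]: -0.5}
    table = FragmentTable(values, unseen_value=0.0, radius=2)
    assert table.score("CCO") == pytest.approx(1.5)


def test_empty_molecule_scores_zero():
    from rdkit import Chem
    table = FragmentTable({}, unseen_value=5.0, radius=2)
    assert table.score_mol(Chem.MolFromSmiles("")) == 0.0


def test_smoothed_log_likelihood_ratio_hand_value():
    """A fragment in 3/4 easy and 1/4 hard molecules scores ln 2 (p=1)."""
    easy = ["C", "C", "C", "O"]     # methane env in 3 of 4
    hard = ["C", "O", "O", "O"]     # methane env in 1 of 4
    table = FragmentTable.train(easy, hard, pseudocount=1.0, radius=2)
    assert table.score("C") == pytest.approx(math.log(2), abs=1e-12)


def test_unseen_fragment_contributes_smoothed_value_not_error():
    table = FragmentTable.train(["CC"], ["CCCC"], pseudocount=1.0)
    # benzene shares no fragments with the training chains
    score = table.score("c1ccccc1")
    n_frags = len(FragmentTable.fragments_of(
        __import__("rdkit").Chem.MolFromSmiles("c1ccccc1"), 2))
    assert score == pytest.approx(n_frags * table.unseen_value)


def test_table_separates_synthetic_easy_and_hard_sets():
    easy, hard = make_easy_hard_sets(rng_seed=1)
    table = FragmentTable.train(easy, hard)
    mean_easy = sum(table.score(s) for s in easy) / len(easy)
    mean_hard = sum(table.score(s) for s in hard) / len(hard)
    assert mean_easy > 0 > mean_hard


def test_table_serialization_bit_exact(tmp_path):
    table = FragmentTable.train(["CCO", "CCN"], ["c1ccc2ccccc2c1"])
    table.save(tmp_path / "t.csv", tmp_path / "t.json")
    reloaded = FragmentTable.load(tmp_path / "t.csv", tmp_path / "t.json")
    assert reloaded.values == table.values
    assert reloaded.unseen_value == table.unseen_value
    assert reloaded.radius == table.radius


# -- normalization and "My score" ------------------------------------------

def test_minmax_endpoints_and_my_score_formula():
    """QED 0.80 -> 1.00 and 0.52 -> 0.00 over the reference span."""
    qeds = [0.80, 0.79, 0.69, 0.66, 0.52]
    syns = [140.57, 119.44, 119.78, 116.61, 5.72]
    panels = {f"m{i}": panel(qed=q, syn=s)
              for i, (q, s) in enumerate(zip(qeds, syns))}
    cards = dict(normalize_and_rank(panels))
    assert cards["m0"].qed_norm == pytest.approx(1.00)
    assert cards["m4"].qed_norm == pytest.approx(0.00)
    assert cards["m4"].syn_norm == pytest.approx(0.00)
    assert cards["m4"].my_score == pytest.approx(0.00)
    for card in cards.values():
        assert card.my_score == pytest.approx(
            100.0 * (card.qed_norm + card.syn_norm) / 2.0)


def test_extremes_of_my_score():
    panels = {"lo": panel(qed=0.2, syn=-5.0), "hi": panel(qed=0.9, syn=50.0)}
    cards = dict(normalize_and_rank(panels))
    assert cards["hi"].my_score == pytest.approx(100.0)
    assert cards["lo"].my_score == pytest.approx(0.0)


def test_ranking_sorted_descending():
    panels = {f"m{i}": panel(qed=q, syn=s)
              for i, (q, s) in enumerate([(0.5, 1.0), (0.9, 9.0),
                                          (0.7, 5.0)])}
    ranked = normalize_and_rank(panels)
    scores = [card.my_score for _, card in ranked]
    assert scores == sorted(scores, reverse=True)


def test_my_score_invariant_under_affine_rescaling():
    panels = {f"m{i}": panel(qed=q, syn=s)
              for i, (q, s) in enumerate([(0.5, 1.0), (0.9, 9.0),
                                          (0.7, 5.0)])}
    rescaled = {k: panel(qed=p.qed, syn=3.0 * p.syn_score + 7.0)
                for k, p in panels.items()}
    orig = dict(normalize_and_rank(panels))
    new = dict(normalize_and_rank(rescaled))
    for key in panels:
        assert new[key].my_score == pytest.approx(orig[key].my_score)


def test_degenerate_reference_rejected_except_single_candidate():
    constant = {f"m{i}": panel(qed=0.5, syn=1.0) for i in range(3)}
    with pytest.raises(ValueError):
        normalize_and_rank(constant)
    single = dict(normalize_and_rank({"m": panel(qed=0.5, syn=1.0)}))
    assert single["m"].my_score == 0.0


def test_explicit_reference_set_widens_normalization():
    panels = {"a": panel(qed=0.6, syn=4.0)}
    reference = [panel(qed=0.0, syn=-192.0), panel(qed=1.0, syn=128.0)]
    cards = dict(normalize_and_rank(panels, reference=reference))
    assert cards["a"].qed_norm == pytest.approx(0.6)
    assert cards["a"].syn_norm == pytest.approx((4.0 + 192.0) / 320.0)


# -- cascade ----------------------------------------------------------------

def test_cascade_thresholds_and_boundaries():
    panels = {
        "qed_low": panel(qed=0.49), "qed_ok": panel(qed=0.51),
        "syn_neg": panel(syn=-0.01), "syn_zero": panel(syn=0.0),
        "syn_pos": panel(syn=0.01), "heavy": panel(mw=600.0),
    }
    survivors, report = filter_cascade(panels)
    assert "qed_low" not in survivors and "heavy" not in survivors
    assert "syn_neg" not in survivors
    assert {"qed_ok", "syn_zero", "syn_pos"} <= set(survivors)
    assert report.n_input == 6
    assert report.n_pass_all <= min(report.n_pass_qed, report.n_pass_ro5,
                                    report.n_pass_syn)


def test_cascade_order_invariance():
    """Filters are independent predicates: any stage order agrees."""
    panels = {f"m{i}": panel(qed=q, syn=s, mw=m)
              for i, (q, s, m) in enumerate(
                  [(0.6, 1.0, 300), (0.4, 2.0, 300), (0.8, -1.0, 300),
                   (0.9, 3.0, 700), (0.55, 0.0, 450)])}
    survivors, _ = filter_cascade(panels)
    predicates = [lambda p: p.qed >= 0.5, lambda p: ro5_pass(p),
                  lambda p: p.syn_score >= 0.0]
    for order in itertools.permutations(predicates):
        keys = list(panels)
        for pred in order:
            keys = [k for k in keys if pred(panels[k])]
        assert keys == survivors


def test_reporting_arithmetic_matches_printed_rates():
    assert CascadeReport.percent(26, 55) == 47.27
    assert CascadeReport.percent(25, 78) == 32.05
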