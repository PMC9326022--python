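"""Mining: PR and f-score formulas, thresholds, dedup, serialization."""

import json
import random
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from structalert.catalog import SubstructureCatalog
from structalert.chem import dataset_from_smiles
from structalert.matching import compile_smarts, has_match
from structalert.mining import (
    F_SCORE_SENTINEL,
    AlertSetSchemaError,
    FragmentStats,
    MiningError,
    StructuralAlert,
    AlertSet,
    f_score,
    import_smarts_list,
    load_alert_set,
    merge_alert_sets,
    mine_fp_filter,
    mine_sarpy,
    positive_rate,
    save_alert_set,
)

from conftest import make_boundary_dataset, oracle_f_score, planted_fixture  # noqa: F401


# --- positive rate ---------------------------------------------------------

@pytest.mark.parametrize("n_pos,n,expected", [(6, 8, 0.75), (8, 8, 1.0), (0, 5, 0.0)])
def test_positive_rate_examples(n_pos, n, expected):
    assert positive_rate(n_pos, n) == expected


def test_positive_rate_zero_carriers_undefined():
    with pytest.raises(MiningError):
        positive_rate(0, 0)


# --- f-score ---------------------------------------------------------------

def test_f_score_constant_feature_is_zero():
    assert f_score([1, 1, 1, 1], [1, 1, 0, 0]) == 0.0
    assert f_score([0, 0, 0, 0], [1, 0, 1, 0]) == 0.0


def test_f_score_perfect_separator_hits_sentinel():
    presence = [1] * 5 + [0] * 5
    labels = [1] * 5 + [0] * 5
    assert f_score(presence, labels) == F_SCORE_SENTINEL


def test_f_score_hand_cross_check():
    presence = [1, 1, 1, 0, 0, 0]
    labels = [1, 1, 0, 1, 0, 0]
    expected = oracle_f_score(presence, labels)
    assert expected is not None
    assert f_score(presence, labels) == pytest.approx(float(expected), rel=1e-12)


def test_f_score_single_class_rejected():
    with pytest.raises(MiningError):
        f_score([1, 0], [1, 1])


@settings(derandomize=True, max_examples=300)
@given(st.integers(0, 2**32 - 1))
def test_f_score_matches_oracle_on_random_vectors(seed):
    rng = random.Random(seed)
    n = rng.randint(4, 30)
    labels = [1, 0] + [rng.randint(0, 1) for _ in range(n - 2)]
    presence = [rng.randint(0, 1) for _ in range(n)]
    expected = oracle_f_score(presence, labels)
    got = f_score(presence, labels)
    if expected is None:
        assert got == F_SCORE_SENTINEL
    else:
        assert got == pytest.approx(float(expected), rel=1e-12, abs=1e-15)


# --- fingerprints-filter mining --------------------------------------------

NITRO = "[N+](=O)[O-]"


def test_fp_filter_recovers_planted_alert(planted_fixture):
    dataset, manifest = planted_fixture
    catalog = SubstructureCatalog.from_smarts([NITRO, "C(=O)O"], name="t")
    alerts = mine_fp_filter(dataset, catalog)
    assert alerts.smarts_list() == [NITRO]
    stats = alerts.alerts[0].stats
    planted = manifest["planted_alerts"][0]
    assert stats.n_fragment == planted["realized_support"]
    assert stats.n_fragment_positive == planted["realized_positive"]
    assert stats.pr == pytest.approx(planted["realized_pr"])


def test_fp_filter_hand_count_oracle(planted_fixture):
    """Stored stats equal brute-force recounts over the dataset."""
    dataset, _ = planted_fixture
    catalog = SubstructureCatalog.from_smarts([NITRO, "C(=O)O", "c1ccccc1"], name="t")
    alerts = mine_fp_filter(dataset, catalog, min_support=1, min_f=0.0, min_pr=0.0)
    assert len(alerts) >= 2
    for alert in alerts:
        query = compile_smarts(alert.smarts)
        carriers = [c for c in dataset if has_match(c.mol(), query)]
        assert alert.stats.n_fragment == len(carriers)
        assert alert.stats.n_fragment_positive == sum(c.label for c in carriers)


def test_fp_filter_support_boundary():
    """Support exactly 6 is retained; 5 is excluded."""
    catalog = SubstructureCatalog.from_smarts([NITRO], name="t")
    at6 = mine_fp_filter(make_boundary_dataset(6, 6), catalog)
    assert at6.smarts_list() == [NITRO]
    at5 = mine_fp_filter(make_boundary_dataset(5, 5), catalog)
    assert at5.smarts_list() == []


def test_fp_filter_pr_boundary():
    """PR exactly 13/20 = 0.65 is retained; 12/20 = 0.60 is excluded."""
    catalog = SubstructureCatalog.from_smarts([NITRO], name="t")
    at_boundary = mine_fp_filter(make_boundary_dataset(20, 13), catalog)
    assert at_boundary.smarts_list() == [NITRO]
    assert at_boundary.alerts[0].stats.pr == pytest.approx(0.65)
    below = mine_fp_filter(make_boundary_dataset(20, 12), catalog)
    assert below.smarts_list() == []


def test_fp_filter_single_class_rejected():
    dataset, _ = dataset_from_smiles(["CCO", "CCC"], [1, 1])
    with pytest.raises(MiningError):
        mine_fp_filter(dataset, SubstructureCatalog.from_smarts(["C"], name="t"))


# --- SARpy-style mining ----------------------------------------------------

def test_sarpy_recovers_planted_aromatic_amine():
    """5 toxic aniline derivatives vs 10 clean non-toxics."""
    toxic = ["Nc1ccccc1", "Nc1ccccc1C", "Nc1ccccc1CC", "Nc1ccccc1O", "Nc1ccccc1CO"]
    clean = ["CCO", "CCC", "CCCC", "CCOCC", "C1CCCCC1",
             "CC(C)O", "CCCO", "CCCCC", "C1CCOC1", "CC(C)C"]
    dataset, _ = dataset_from_smiles(toxic + clean, [1] * 5 + [0] * 10)
    alerts = mine_sarpy(dataset, max_atoms=10)
    assert len(alerts) >= 1
    amine_query = compile_smarts("Nc1ccccc1")
    perfect = [a for a in alerts if a.stats.pr == 1.0]
    assert perfect
    # the aromatic-amine signal (or a dominating sub-fragment) is present:
    # every toxic compound matches some perfect alert
    for smiles in toxic:
        from rdkit import Chem
        mol = Chem.MolFromSmiles(smiles)
        assert any(has_match(mol, compile_smarts(a.smarts)) for a in perfect)


def test_sarpy_empty_on_tiny_molecules():
    dataset, _ = dataset_from_smiles(["C", "O=C=O", "CO"], [1, 1, 0])
    alerts = mine_sarpy(dataset, min_atoms=2, min_support=3)
    assert len(alerts) == 0


def test_sarpy_dominance_pruning():
    """Every pruned pattern has a kept sub-pattern at least as predictive."""
    toxic = ["Nc1ccccc1", "Nc1ccccc1C", "Nc1ccccc1CC", "Nc1ccccc1O", "Nc1ccccc1CO"]
    clean = ["CCO", "CCC", "CCCC", "CCOCC", "C1CCCCC1",
             "CC(C)O", "CCCO", "CCCCC", "C1CCOC1", "CC(C)C"]
    dataset, _ = dataset_from_smiles(toxic + clean, [1] * 5 + [0] * 10)
    pruned_set = mine_sarpy(dataset, max_atoms=10, prune_dominated=True)
    full_set = mine_sarpy(dataset, max_atoms=10, prune_dominated=False)
    kept = {a.smarts: a for a in pruned_set}
    assert set(kept) <= {a.smarts for a in full_set}
    from rdkit import Chem
    from structalert.mining import _pattern_as_mol

    for alert in full_set:
        if alert.smarts in kept:
            continue
        outer = _pattern_as_mol(alert.smarts)
        dominators = [
            k for k in pruned_set
            if Fraction(k.stats.n_fragment_positive, k.stats.n_fragment)
            >= Fraction(alert.stats.n_fragment_positive, alert.stats.n_fragment)
            and (outer is None or has_match(outer, compile_smarts(k.smarts)))
        ]
        assert dominators, alert.smarts


# --- merge, serialization --------------------------------------------------

def _alert(smarts, endpoint="ep", origin="fp_filter", n=10, npos=8):
    return StructuralAlert(
        alert_id=f"x_{smarts}", smarts=smarts, endpoint=endpoint, origin=origin,
        stats=FragmentStats(n, npos, npos / n),
    )


def test_merge_dedup_and_identity():
    a = AlertSet("ep", [_alert("C=O"), _alert("CN")])
    b = AlertSet("ep", [_alert("C=O", origin="sarpy", n=12, npos=9), _alert("CCl")])
    merged = merge_alert_sets([a, b])
    assert len(merged) == 3  # |A| + |B| - 1
    winner = next(x for x in merged if x.smarts == "C=O")
    assert winner.stats.n_fragment == 12  # larger support wins
    empty_merge = merge_alert_sets([a])
    assert [x.smarts for x in empty_merge] == [x.smarts for x in merge_alert_sets([a, AlertSet("ep", [])])]


def test_merge_order_insensitive():
    sets = [
        AlertSet("ep", [_alert("C=O"), _alert("CN")]),
        AlertSet("ep", [_alert("CCl", n=4, npos=4)]),
        AlertSet("ep", [_alert("C=O", origin="sarpy", n=10, npos=8)]),
    ]
    import itertools

    reference = None
    for perm in itertools.permutations(sets):
        merged = merge_alert_sets(list(perm))
        key = [(x.smarts, x.origin, x.stats.n_fragment) for x in merged]
        if reference is None:
            reference = key
        assert key == reference


def test_merge_endpoint_mismatch():
    with pytest.raises(MiningError):
        merge_alert_sets([AlertSet("a", [_alert("C")]), AlertSet("b", [_alert("C")])])


def test_save_load_roundtrip(tmp_path, planted_fixture):
    dataset, _ = planted_fixture
    catalog = SubstructureCatalog.from_smarts([NITRO, "C(=O)O"], name="t")
    alerts = mine_fp_filter(dataset, catalog)
    path = tmp_path / "alerts.json"
    save_alert_set(alerts, path)
    loaded = load_alert_set(path)
    assert loaded.endpoint == alerts.endpoint
    assert [(a.alert_id, a.smarts, a.origin, a.stats) for a in loaded] == [
        (a.alert_id, a.smarts, a.origin, a.stats) for a in alerts
    ]
    # byte-identical re-save
    path2 = tmp_path / "alerts2.json"
    save_alert_set(loaded, path2)
    assert path.read_bytes() == path2.read_bytes()


def test_load_missing_field_names_json_path(tmp_path):
    doc = {"endpoint": "ep", "alerts": [{"alert_id": "a0", "origin": "imported"}]}
    path = tmp_path / "bad.json"
    path.write_text(json.dumps(doc))
    with pytest.raises(AlertSetSchemaError, match=r"\$\.alerts\[0\]\.smarts"):
        load_alert_set(path)


def test_import_plain_smarts_list(tmp_path):
    path = tmp_path / "alerts.smarts"
    path.write_text("C=O\n[N+](=O)[O-]\t# nitro\nC=O\n")
    imported = import_smarts_list(path, "ep")
    assert len(imported) == 2  # duplicate line collapsed
    assert all(a.origin == "imported" and a.stats is None for a in imported)
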