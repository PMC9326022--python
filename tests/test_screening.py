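"""Screening: embeddings vs the VF2 oracle, verdict rule, AD flagging."""

import pytest
from rdkit import Chem

from structalert.catalog import (
    BinaryFingerprint,
    CatalogError,
    SubstructureCatalog,
    compute_fingerprint,
)
from structalert.chem import dataset_from_smiles
from structalert.mining import AlertSet, StructuralAlert
from structalert.screening import (
    DomainModel,
    in_domain,
    load_domain_model,
    match_alert,
    save_domain_model,
    screen,
    screen_batch,
)

from conftest import PATTERN_PANEL, as_compound, oracle_embeddings


def _alert_set(smarts_list, endpoint="ep"):
    alerts = [
        StructuralAlert(f"ep_imported_{i:04d}", s, endpoint, "imported")
        for i, s in enumerate(smarts_list)
    ]
    return AlertSet(endpoint, alerts)


def test_toluene_single_benzene_embedding():
    matches = match_alert(as_compound("Cc1ccccc1"), "c1ccccc1")
    assert len(matches) == 1
    assert len(matches[0]) == 6


def test_no_match_is_empty():
    assert match_alert(as_compound("CCO"), "[N+](=O)[O-]") == ()


def test_biphenyl_two_embeddings():
    compound = as_compound("c1ccc(-c2ccccc2)cc1")
    matches = match_alert(compound, "c1ccccc1")
    atom_sets = {frozenset(m) for m in matches}
    assert len(atom_sets) == 2
    assert all(len(s) == 6 for s in atom_sets)
    assert not (set.intersection(*map(set, atom_sets)))
    # agrees with the independent subgraph-embedding oracle
    assert atom_sets == oracle_embeddings(compound.mol(), "c1ccccc1")


def test_matcher_agrees_with_vf2_oracle(molecule_panel):
    """Embeddings equal brute-force subgraph monomorphisms on the full panel."""
    for mol in molecule_panel:
        for pattern in PATTERN_PANEL:
            got = {frozenset(m) for m in match_alert(mol, pattern)}
            expected = oracle_embeddings(mol, pattern)
            assert got == expected, (Chem.MolToSmiles(mol), pattern)


def test_match_atom_indices_valid(molecule_panel):
    for mol in molecule_panel:
        for pattern in PATTERN_PANEL:
            for embedding in match_alert(mol, pattern):
                assert all(0 <= i < mol.GetNumAtoms() for i in embedding)


def test_screen_verdict_match_consistency():
    alert_set = _alert_set(["[N+](=O)[O-]", "c1ccccc1"])
    for smiles in ["O=[N+]([O-])C1CCCCC1", "CCO", "Cc1ccccc1", "CCCC"]:
        result = screen(as_compound(smiles), alert_set)
        assert (result.verdict == "positive") == (len(result.matches) > 0)


def test_screen_negative_has_no_matches():
    result = screen(as_compound("CCO"), _alert_set(["[N+](=O)[O-]"]))
    assert result.verdict == "negative" and result.matches == ()


def test_screen_monotone_in_alert_set():
    """Adding alerts never flips positive to negative."""
    small = _alert_set(["[N+](=O)[O-]"])
    large = _alert_set(["[N+](=O)[O-]", "c1ccccc1", "C=O"])
    for smiles in ["O=[N+]([O-])CC", "CCO", "c1ccccc1", "CC=O"]:
        small_verdict = screen(as_compound(smiles), small).verdict
        large_verdict = screen(as_compound(smiles), large).verdict
        if small_verdict == "positive":
            assert large_verdict == "positive"


# --- applicability domain --------------------------------------------------

@pytest.fixture
def domain():
    catalog = SubstructureCatalog.from_smarts(
        ["c1ccccc1", "[OX2H]", "N", "C=O", "CC"], name="ad"
    )
    dataset, _ = dataset_from_smiles(
        ["Oc1ccccc1", "Nc1ccccc1", "CCO", "CC(C)=O"], [1, 1, 0, 0]
    )
    return DomainModel.from_dataset(dataset, catalog)


def test_in_domain_inclusive_at_cutoff():
    catalog = SubstructureCatalog.from_smarts(["C", "N", "O", "S"], name="c4")
    fp_train = BinaryFingerprint("c4", frozenset({0, 1, 2}))
    model = DomainModel(catalog=catalog, training_fingerprints=[("t", fp_train)],
                        cutoff=0.5)
    query = BinaryFingerprint("c4", frozenset({1, 2, 3}))  # Tc = 2/4 = 0.5
    flag, tc, nearest = in_domain(query, model)
    assert tc == pytest.approx(0.5)
    assert flag is True
    assert nearest == "t"


def test_out_of_domain_when_no_shared_bits(domain):
    fp = BinaryFingerprint("ad", frozenset())
    flag, tc, _ = in_domain(fp, domain)
    assert flag is False and tc == 0.0


def test_training_compound_is_in_domain(domain):
    fp = compute_fingerprint("Oc1ccccc1", domain.catalog)
    flag, tc, nearest = in_domain(fp, domain)
    assert flag is True and tc == 1.0
    assert nearest == next(
        cid for cid, t in domain.training_fingerprints if t.bits == fp.bits
    )


def test_in_domain_catalog_mismatch(domain):
    with pytest.raises(CatalogError):
        in_domain(BinaryFingerprint("other", frozenset({0})), domain)


def test_screen_with_domain_advisory(domain):
    alert_set = _alert_set(["[N+](=O)[O-]"])
    result = screen(as_compound("O=[N+]([O-])C1CCC1"), alert_set, domain)
    # verdict reported even when out of domain: the flag is advisory
    assert result.verdict == "positive"
    assert result.in_domain in (True, False)
    assert 0.0 <= result.max_similarity <= 1.0


# --- batch -----------------------------------------------------------------

def test_screen_batch_shape_and_error_rows():
    sets = [_alert_set(["[N+](=O)[O-]"], "ep1"), _alert_set(["c1ccccc1"], "ep2")]
    queries = [("q1", "O=[N+]([O-])CC"), ("q2", "not)a(smiles"), ("q3", "Cc1ccccc1")]
    frame = screen_batch(queries, sets)
    # 2 valid queries x 2 endpoints + 1 error row
    assert len(frame) == 5
    errors = frame[frame.verdict.str.startswith("error")]
    assert list(errors.query_id) == ["q2"]
    q3 = frame[(frame.query_id == "q3") & (frame.endpoint == "ep2")]
    assert list(q3.verdict) == ["positive"]


def test_screen_batch_empty_alert_set_all_negative():
    frame = screen_batch([("a", "CCO"), ("b", "c1ccccc1")], [AlertSet("ep", [])])
    assert set(frame.verdict) == {"negative"}


def test_screen_batch_ad_gate(domain):
    sets = [_alert_set(["[N+](=O)[O-]"])]
    # perfluorinated ether shares no catalog keys: out of domain, gated
    frame = screen_batch(
        [("far", "FC(F)(F)OC(F)(F)F")], sets, [domain], ad_gate=True
    )
    assert list(frame.verdict) == ["no_prediction"]
    assert list(frame.in_domain) == [False]


def test_domain_model_roundtrip(tmp_path, domain):
    path = tmp_path / "domain.json"
    save_domain_model(domain, path)
    loaded = load_domain_model(path)
    assert loaded.cutoff == domain.cutoff
    assert loaded.catalog.name == domain.catalog.name
    assert [
        (cid, fp.bits) for cid, fp in loaded.training_fingerprints
    ] == [(cid, fp.bits) for cid, fp in domain.training_fingerprints]
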