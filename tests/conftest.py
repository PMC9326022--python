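"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: the
embedding oracle enumerates subgraph monomorphisms with networkx VF2,
the fragment oracle enumerates bond-cut subsets exhaustively, and the
metric oracles work in exact rational arithmetic.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import networkx as nx
import pytest
from rdkit import Chem

from structalert.chem import Compound, dataset_from_smiles, standardize_compound

# --- panels ----------------------------------------------------------------

# 25 molecules; the first block is <=8 heavy atoms (used by the fragment
# enumeration oracle), the rest exercise the matcher on larger structures.
MOLECULE_PANEL = [
    "CCO", "CCC", "CC(C)O", "c1ccccc1", "C[N+](=O)[O-]",
    "CC(=O)O", "C1CCCCC1", "C1CCOC1", "c1ccncc1", "c1cc[nH]c1",
    "C1CO1", "CC#N", "CCCl", "C=CC=O", "NCCO",
    "CSC", "OCC(O)CO", "CC(C)(C)C", "C1CCNC1", "CCOCC",
    "Cc1ccccc1", "Oc1ccccc1", "Nc1ccccc1", "O=[N+]([O-])c1ccccc1",
    "c1ccc(-c2ccccc2)cc1",
]

# 15 SMILES-expressible patterns, each <=8 heavy atoms, no H-count or
# charge-wildcard subtleties beyond "unbracketed atom matches any charge".
PATTERN_PANEL = [
    "CC", "CO", "CN", "C=O", "C#N",
    "CCl", "CS", "OCCO", "C1CO1", "C=CC=O",
    "c1ccccc1", "c1ccncc1", "Nc1ccccc1", "Oc1ccccc1", "[N+](=O)[O-]",
]


@pytest.fixture(scope="session")
def molecule_panel() -> list[Chem.Mol]:
    return [Chem.MolFromSmiles(s) for s in MOLECULE_PANEL]


@pytest.fixture(scope="session")
def small_molecule_panel() -> list[Chem.Mol]:
    mols = [Chem.MolFromSmiles(s) for s in MOLECULE_PANEL]
    return [m for m in mols if m.GetNumHeavyAtoms() <= 8]


# --- embedding oracle (networkx VF2 subgraph monomorphism) -----------------

def _mol_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(
            atom.GetIdx(),
            z=atom.GetAtomicNum(),
            arom=atom.GetIsAromatic(),
            charge=atom.GetFormalCharge(),
        )
    for bond in mol.GetBonds():
        label = "arom" if bond.GetIsAromatic() else bond.GetBondTypeAsDouble()
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), label=label)
    return g


def oracle_embeddings(mol: Chem.Mol, pattern_smiles: str) -> set[frozenset[int]]:
    """All distinct atom-index sets where the pattern embeds in the molecule.

    The pattern is parsed as SMILES to fix its bond orders; node
    matching requires equal element and aromaticity, and equal charge
    only when the pattern atom carries an explicit charge (an uncharged
    pattern atom is a charge wildcard, the substructure-query
    convention for unbracketed atoms).
    """
    pattern = Chem.MolFromSmiles(pattern_smiles)
    assert pattern is not None, pattern_smiles
    pg, mg = _mol_graph(pattern), _mol_graph(mol)

    def node_match(m_attrs, p_attrs):
        if m_attrs["z"] != p_attrs["z"] or m_attrs["arom"] != p_attrs["arom"]:
            return False
        return p_attrs["charge"] == 0 or m_attrs["charge"] == p_attrs["charge"]

    def edge_match(m_attrs, p_attrs):
        return m_attrs["label"] == p_attrs["label"]

    matcher = nx.algorithms.isomorphism.GraphMatcher(
        mg, pg, node_match=node_match, edge_match=edge_match
    )
    return {frozenset(mapping) for mapping in matcher.subgraph_monomorphisms_iter()}


# --- fragment enumeration oracle (exhaustive bond-cut subsets) -------------

def _oracle_cuttable(mol: Chem.Mol) -> list[int]:
    ring_info = mol.GetRingInfo()
    return [
        b.GetIdx() for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE
        and not b.GetIsAromatic()
        and ring_info.NumBondRings(b.GetIdx()) == 0
    ]


def oracle_fragments(mol: Chem.Mol, min_atoms: int, max_atoms: int) -> set[str]:
    """Canonical fragment patterns from every subset of cuttable bonds.

    Exponential in the cuttable-bond count; only usable on small
    molecules, which is exactly its role.
    """
    cuttable = _oracle_cuttable(mol)
    n = mol.GetNumAtoms()
    patterns: set[str] = set()
    for r in range(len(cuttable) + 1):
        for cut in itertools.combinations(cuttable, r):
            cut_set = set(cut)
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for bond in mol.GetBonds():
                if bond.GetIdx() not in cut_set:
                    a, b = find(bond.GetBeginAtomIdx()), find(bond.GetEndAtomIdx())
                    if a != b:
                        parent[a] = b
            components: dict[int, list[int]] = {}
            for i in range(n):
                components.setdefault(find(i), []).append(i)
            for atoms in components.values():
                if not min_atoms <= len(atoms) <= max_atoms:
                    continue
                bonds = [
                    b.GetIdx() for b in mol.GetBonds()
                    if b.GetBeginAtomIdx() in atoms and b.GetEndAtomIdx() in atoms
                ]
                patterns.add(Chem.MolFragmentToSmiles(
                    mol, atomsToUse=atoms, bondsToUse=bonds or None,
                    canonical=True, isomericSmiles=False,
                ))
    return patterns


# --- exact-rational metric oracles -----------------------------------------

def oracle_f_score(presence, labels) -> Fraction | None:
    """Fisher feature score in exact rationals; None encodes the infinite case."""
    pos = [Fraction(p) for p, y in zip(presence, labels) if y == 1]
    neg = [Fraction(p) for p, y in zip(presence, labels) if y == 0]
    m_pos = sum(pos) / len(pos)
    m_neg = sum(neg) / len(neg)
    m_all = Fraction(sum(presence), len(presence))

    def var(vals, mean):
        if len(vals) <= 1:
            return Fraction(0)
        return sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)

    numer = (m_pos - m_all) ** 2 + (m_neg - m_all) ** 2
    denom = var(pos, m_pos) + var(neg, m_neg)
    if denom == 0:
        return Fraction(0) if numer == 0 else None
    return numer / denom


def oracle_metrics(tp, fp, tn, fn) -> dict[str, Fraction | None]:
    def ratio(a, b):
        return None if b == 0 else Fraction(a, b)

    return {
        "q": ratio(tp + tn, tp + fp + tn + fn),
        "se": ratio(tp, tp + fn),
        "sp": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
    }


# --- shared datasets -------------------------------------------------------

def make_boundary_dataset(n_carriers: int, n_carrier_pos: int, n_background: int = 20,
                          n_background_pos: int = 8):
    """Dataset where exactly n_carriers nitroalkanes carry the nitro key.

    Carrier structures are distinct-length nitroalkanes; background
    compounds are alcohols and alkanes free of the key.  Used to place a
    pattern exactly on (or just below) a mining threshold.
    """
    smiles, labels = [], []
    for i in range(n_carriers):
        smiles.append("O=[N+]([O-])" + "C" * (i + 1))
        labels.append(1 if i < n_carrier_pos else 0)
    for i in range(n_background):
        smiles.append("OC" + "C" * (i + 1) if i % 2 == 0 else "C" * (i + 2))
        labels.append(1 if i < n_background_pos else 0)
    dataset, rejections = dataset_from_smiles(smiles, labels, endpoint="boundary")
    assert not rejections
    return dataset


@pytest.fixture(scope="session")
def planted_fixture():
    """A seeded 40-compound dataset with one strong planted nitro alert."""
    from structalert.synthetic import FixtureSpec, PlantedAlert, generate_dataset

    spec = FixtureSpec(
        seed=7, n_compounds=40,
        planted_alerts=[PlantedAlert("[N+](=O)[O-]", 0.25, 0.9)],
        decoys=["C(=O)O"], label_noise=0.0, endpoint="fixture",
    )
    return generate_dataset(spec)


def as_compound(smiles: str, compound_id: str = "q") -> Compound:
    c = standardize_compound(smiles, compound_id=compound_id)
    assert isinstance(c, Compound), f"{smiles} rejected"
    return c
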