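"""Exhaustive fragment enumeration by acyclic single-bond cleavage.

A fragment is any connected piece obtainable by cutting some subset of
the molecule's acyclic, single, non-aromatic bonds.  Rings (and double,
triple, and aromatic bonds) are never opened, so every fragment is an
honest substructure of its parent.  Because all cuttable bonds are
acyclic, contracting the uncuttable bonds turns the molecule into a
forest whose connected node-subsets are exactly the fragments; the
enumeration walks that forest instead of the exponential set of
bond-cut subsets.

Patterns are canonical fragment SMILES (stereo dropped): the same
chemical fragment enumerated from different parents yields a
byte-identical pattern, which is what cross-compound support counting
relies on.  Interpreted as SMARTS, a pattern matches any molecule that
embeds the fragment with arbitrary substitution at the cut positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

from rdkit import Chem

from .chem import Compound, Dataset
from .matching import compile_smarts

DEFAULT_MIN_ATOMS = 2
DEFAULT_MAX_ATOMS = 18
DEFAULT_FRAGMENT_CAP = 10_000


@dataclass(frozen=True)
class Fragment:
    """A canonical fragment pattern with the compounds it was cut from."""

    pattern: str
    atom_count: int
    parent_ids: frozenset[str]

    def to_query(self) -> Chem.Mol:
        return compile_smarts(self.pattern)


def fragment_to_smarts(fragment: Fragment) -> str:
    """The SMARTS form of a fragment: its pattern, validated to parse.

    Cut positions carry no constraint — the pattern matches the fragment
    embedded in any environment, so every parent compound matches its
    own fragments.
    """
    compile_smarts(fragment.pattern)
    return fragment.pattern


def _cuttable_bonds(mol: Chem.Mol) -> list[Chem.Bond]:
    ring_info = mol.GetRingInfo()
    out = []
    for bond in mol.GetBonds():
        if (bond.GetBondType() == Chem.BondType.SINGLE
                and not bond.GetIsAromatic()
                and ring_info.NumBondRings(bond.GetIdx()) == 0):
            out.append(bond)
    return out


def _contract(mol: Chem.Mol) -> tuple[list[list[int]], list[set[int]]]:
    """Contract uncuttable bonds: returns (node -> atom list, adjacency)."""
    n = mol.GetNumAtoms()
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    cuttable = {b.GetIdx() for b in _cuttable_bonds(mol)}
    for bond in mol.GetBonds():
        if bond.GetIdx() not in cuttable:
            a, b = find(bond.GetBeginAtomIdx()), find(bond.GetEndAtomIdx())
            if a != b:
                parent[a] = b
    roots = sorted({find(i) for i in range(n)})
    index = {r: k for k, r in enumerate(roots)}
    nodes: list[list[int]] = [[] for _ in roots]
    for i in range(n):
        nodes[index[find(i)]].append(i)
    adj: list[set[int]] = [set() for _ in roots]
    for bond in mol.GetBonds():
        if bond.GetIdx() in cuttable:
            u = index[find(bond.GetBeginAtomIdx())]
            v = index[find(bond.GetEndAtomIdx())]
            if u != v:
                adj[u].add(v)
                adj[v].add(u)
    return nodes, adj


def _connected_subsets(
    adj: list[set[int]], weights: list[int], max_weight: int, cap: int
) -> tuple[list[frozenset[int]], bool]:
    """All connected node-subsets of a forest with total weight ≤ max_weight.

    BFS over subsets with explicit dedup; expansion is pruned as soon as
    a subset exceeds the weight bound (supersets only grow).  Returns
    (subsets, cap_hit).
    """
    n = len(adj)
    seen: set[frozenset[int]] = set()
    queue: list[frozenset[int]] = []
    for v in range(n):
        if weights[v] <= max_weight:
            s = frozenset([v])
            seen.add(s)
            queue.append(s)
    out: list[frozenset[int]] = []
    cap_hit = False
    while queue:
        current = queue.pop()
        out.append(current)
        if len(out) >= cap:
            cap_hit = True
            break
        w = sum(weights[v] for v in current)
        for v in current:
            for u in adj[v]:
                if u not in current and w + weights[u] <= max_weight:
                    nxt = current | {u}
                    if nxt not in seen:
                        seen.add(nxt)
                        queue.append(nxt)
    return out, cap_hit


def _fragment_smiles(mol: Chem.Mol, atoms: list[int]) -> str:
    bonds = [
        b.GetIdx() for b in mol.GetBonds()
        if b.GetBeginAtomIdx() in atoms and b.GetEndAtomIdx() in atoms
    ]
    return Chem.MolFragmentToSmiles(
        mol, atomsToUse=atoms, bondsToUse=bonds or None,
        canonical=True, isomericSmiles=False,
    )


def enumerate_fragments(
    compound: Compound | Chem.Mol,
    min_atoms: int = DEFAULT_MIN_ATOMS,
    max_atoms: int = DEFAULT_MAX_ATOMS,
    fragment_cap: int = DEFAULT_FRAGMENT_CAP,
) -> list[Fragment]:
    """Enumerate every fragment of a compound, deduplicated and size-filtered.

    Returns fragments in lexicographic pattern order.  A compound
    smaller than ``min_atoms`` yields the empty list.  When the
    per-molecule ``fragment_cap`` is hit, enumeration stops and a
    warning is emitted.
    """
    if not 1 <= min_atoms <= max_atoms:
        raise ValueError("need 1 <= min_atoms <= max_atoms")
    if isinstance(compound, Compound):
        mol = compound.mol()
        parent_id = compound.compound_id
    else:
        mol = compound
        parent_id = ""
    nodes, adj = _contract(mol)
    weights = [len(a) for a in nodes]
    subsets, cap_hit = _connected_subsets(adj, weights, max_atoms, fragment_cap)
    if cap_hit:
        warnings.warn(
            f"fragment cap {fragment_cap} hit for compound {parent_id!r}; "
            "enumeration truncated", RuntimeWarning, stacklevel=2,
        )
    patterns: dict[str, int] = {}
    for subset in subsets:
        atoms = sorted(a for v in subset for a in nodes[v])
        if not min_atoms <= len(atoms) <= max_atoms:
            continue
        smi = _fragment_smiles(mol, atoms)
        patterns.setdefault(smi, len(atoms))
    parents = frozenset([parent_id]) if parent_id else frozenset()
    return [
        Fragment(pattern=p, atom_count=patterns[p], parent_ids=parents)
        for p in sorted(patterns)
    ]


def fragment_support(
    fragments_by_compound: Mapping[str, Iterable[Fragment]],
    dataset: Dataset | None = None,
    min_support: int = 3,
) -> list[Fragment]:
    """Merge per-compound fragments and keep those in ≥ min_support compounds.

    Identical patterns from different parents merge into one Fragment
    with the union of parent ids.  Output is lexicographic by pattern.
    """
    if dataset is not None:
        known = {c.compound_id for c in dataset}
        missing = set(fragments_by_compound) - known
        if missing:
            raise ValueError(f"fragment map references unknown compounds: {sorted(missing)[:5]}")
    merged: dict[str, tuple[int, set[str]]] = {}
    for cid, frags in fragments_by_compound.items():
        for frag in frags:
            if frag.pattern in merged:
                merged[frag.pattern][1].add(cid)
            else:
                merged[frag.pattern] = (frag.atom_count, {cid})
    return [
        Fragment(pattern=p, atom_count=ac, parent_ids=frozenset(parents))
        for p, (ac, parents) in sorted(merged.items())
        if len(parents) >= min_support
    ]


def write_fragments_csv(fragments: Iterable[Fragment], path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["pattern", "atom_count", "support", "parent_ids"])
        for f in fragments:
            w.writerow([f.pattern, f.atom_count, len(f.parent_ids),
                        "|".join(sorted(f.parent_ids))])
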