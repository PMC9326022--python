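"""Shared substructure-matching semantics.

Every component that asks "does pattern P occur in molecule M" — catalog
fingerprints, alert screening, mining statistics — goes through this one
matcher, so bit presence and alert hits can never disagree.  Embeddings
are deduplicated by atom-index set: symmetry-equivalent mappings of the
same atoms (e.g. the 12 automorphisms of benzene onto itself) collapse
to one match, which is what atom highlighting needs.
"""

from __future__ import annotations

from rdkit import Chem


class SmartsError(ValueError):
    """Raised when a SMARTS pattern cannot be parsed."""


def compile_smarts(smarts: str) -> Chem.Mol:
    """Parse a SMARTS pattern, raising :class:`SmartsError` on failure."""
    if not smarts or not smarts.strip():
        raise SmartsError("empty SMARTS pattern")
    query = Chem.MolFromSmarts(smarts)
    if query is None:
        raise SmartsError(f"unparseable SMARTS: {smarts!r}")
    return query


def substructure_matches(mol: Chem.Mol, query: Chem.Mol) -> tuple[tuple[int, ...], ...]:
    """All distinct embeddings of ``query`` in ``mol`` as atom-index tuples.

    Aromaticity is whatever ``mol`` carries (queries are matched against
    the sanitized, aromaticity-perceived molecule).  Embeddings that
    cover the same atom set are reported once, sorted for determinism.
    """
    raw = mol.GetSubstructMatches(query, uniquify=True, maxMatches=100000)
    seen: dict[frozenset[int], tuple[int, ...]] = {}
    for match in raw:
        key = frozenset(match)
        if key not in seen:
            seen[key] = tuple(match)
    return tuple(sorted(seen.values()))


def has_match(mol: Chem.Mol, query: Chem.Mol) -> bool:
    return mol.HasSubstructMatch(query)
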