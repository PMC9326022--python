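"""Predefined-substructure catalogs and binary substructure-key fingerprints.

A catalog is an ordered list of SMARTS keys (the same role the 4,860-key
Klekota–Roth fingerprint plays in large-scale alert mining); a
fingerprint records which keys occur in a compound, presence-only.
Fingerprints are only comparable within one catalog — the key order is
part of the catalog's identity.  The Tanimoto coefficient over these
bit sets, Tc = Nab / (Na + Nb − Nab), is the similarity measure used
for the applicability domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem

from .chem import Compound
from .matching import SmartsError, compile_smarts, has_match


class CatalogError(ValueError):
    """Raised for empty or unusable catalogs."""


@dataclass(frozen=True)
class CatalogEntry:
    key_index: int
    smarts: str
    label: str = ""


@dataclass(frozen=True)
class ParseReport:
    line: int
    smarts: str
    problem: str


@dataclass
class SubstructureCatalog:
    """An ordered, versioned list of SMARTS substructure keys."""

    name: str
    entries: list[CatalogEntry]
    parse_errors: list[ParseReport] = field(default_factory=list)

    def __post_init__(self):
        if not self.entries:
            raise CatalogError(f"catalog {self.name!r} is empty")
        for i, e in enumerate(self.entries):
            if e.key_index != i:
                raise CatalogError("key_index must be dense 0..K-1")
        self._queries = [compile_smarts(e.smarts) for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def queries(self) -> list[Chem.Mol]:
        return self._queries

    @classmethod
    def from_smarts(cls, patterns: Sequence[str | tuple[str, str]],
                    name: str = "custom") -> "SubstructureCatalog":
        entries = []
        for i, p in enumerate(patterns):
            smarts, label = (p, "") if isinstance(p, str) else p
            entries.append(CatalogEntry(i, smarts, label))
        return cls(name=name, entries=entries)


@dataclass(frozen=True)
class BinaryFingerprint:
    """Presence/absence substructure keys of one compound under one catalog."""

    catalog_name: str
    bits: frozenset[int]

    @property
    def n_bits_set(self) -> int:
        return len(self.bits)


def load_catalog(path: str | Path, name: str | None = None) -> SubstructureCatalog:
    """Load a SMARTS-per-line catalog file.

    Lines are ``SMARTS[<tab>label]``; ``#`` starts a comment.
    Unparseable patterns are reported on the returned catalog's
    ``parse_errors`` (and warned), never silently skipped; duplicate
    SMARTS get a warning but both are kept under distinct indices.
    """
    path = Path(path)
    entries: list[CatalogEntry] = []
    errors: list[ParseReport] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            smarts = parts[0].strip()
            label = parts[1].strip() if len(parts) > 1 else ""
            try:
                compile_smarts(smarts)
            except SmartsError as exc:
                errors.append(ParseReport(lineno, smarts, str(exc)))
                continue
            if smarts in seen:
                warnings.warn(
                    f"{path}:{lineno}: duplicate SMARTS {smarts!r} (kept)",
                    stacklevel=2,
                )
            seen.add(smarts)
            entries.append(CatalogEntry(len(entries), smarts, label))
    if errors:
        warnings.warn(
            f"{path}: {len(errors)} unparseable catalog pattern(s)", stacklevel=2
        )
    if not entries:
        raise CatalogError(f"catalog file {path} contains no valid SMARTS")
    cat = SubstructureCatalog(name=name or path.stem, entries=entries)
    cat.parse_errors = errors
    return cat


def default_catalog() -> SubstructureCatalog:
    """The bundled curated toxicophore catalog (~30 SMARTS keys)."""
    ref = resources.files("structalert.data") / "default_catalog.smarts"
    with resources.as_file(ref) as path:
        return load_catalog(path, name="structalert-default-v1")


def _as_mol(compound: Compound | Chem.Mol | str) -> Chem.Mol:
    if isinstance(compound, Compound):
        return compound.mol()
    if isinstance(compound, str):
        mol = Chem.MolFromSmiles(compound)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {compound!r}")
        return mol
    return compound


def compute_fingerprint(
    compound: Compound | Chem.Mol | str, catalog: SubstructureCatalog
) -> BinaryFingerprint:
    """Bit k is set iff catalog key k has at least one match in the compound."""
    mol = _as_mol(compound)
    bits = frozenset(
        i for i, q in enumerate(catalog.queries()) if has_match(mol, q)
    )
    return BinaryFingerprint(catalog_name=catalog.name, bits=bits)


def tanimoto(a: BinaryFingerprint, b: BinaryFingerprint) -> float:
    """Tc = Nab / (Na + Nb − Nab); two empty fingerprints are defined as 0.

    A featureless pair carries no evidence of similarity, so the 0/0
    case is treated as maximally dissimilar (this matters for the
    applicability domain, where an empty query fingerprint must not be
    declared in-domain).
    """
    if a.catalog_name != b.catalog_name:
        raise CatalogError(
            f"fingerprints from different catalogs: {a.catalog_name!r} vs {b.catalog_name!r}"
        )
    nab = len(a.bits & b.bits)
    denom = len(a.bits) + len(b.bits) - nab
    if denom == 0:
        return 0.0
    return nab / denom


def write_fingerprints_csv(
    fingerprints: Iterable[tuple[str, BinaryFingerprint]], path: str | Path
) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "bits"])
        for cid, fp in fingerprints:
            w.writerow([cid, ";".join(str(b) for b in sorted(fp.bits))])
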