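"""Compound standardization, dataset assembly, and file IO.

Raw SMILES records are standardized into a single canonical dialect
(RDKit canonical SMILES, one run = one dialect) and filtered with the
organic-subset rules used throughout alert mining: multi-component
entries (salts, mixtures), carbon-free structures, and metal-containing
structures are rejected rather than repaired.  Datasets are deduplicated
by canonical SMILES and purged of label conflicts, so every downstream
statistic counts unique, consistently labeled structures.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

# Rejection reasons (typed as module constants; every failure maps to one).
UNPARSEABLE = "unparseable"
MIXTURE = "mixture"
SALT_OR_MULTICOMPONENT = "salt_or_multicomponent"
INORGANIC = "inorganic"
ORGANOMETALLIC = "organometallic"
LABEL_CONFLICT = "label_conflict"
DUPLICATE = "duplicate"

REJECTION_REASONS = frozenset(
    {UNPARSEABLE, MIXTURE, SALT_OR_MULTICOMPONENT, INORGANIC,
     ORGANOMETALLIC, LABEL_CONFLICT, DUPLICATE}
)

# Organic-subset convention: everything outside this set is a metal.
_NONMETALS = frozenset({1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 33, 34, 35, 52, 53})

# Common monoatomic counterions, used only when salt stripping is enabled.
_COUNTERION_SMILES = frozenset(
    {"[Na+]", "[K+]", "[Li+]", "[Cl-]", "[Br-]", "[I-]", "[F-]",
     "[Ca+2]", "[Mg+2]", "[NH4+]"}
)


class DatasetError(ValueError):
    """Raised when a dataset cannot be built (e.g. every record rejected)."""


class FileFormatError(ValueError):
    """Raised for unreadable files or missing required columns."""


@dataclass(frozen=True)
class CompoundRecord:
    """One raw data point: a supplied structure string with a binary label."""

    record_id: str
    smiles_raw: str
    label: int
    endpoint: str = ""

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if not self.smiles_raw:
            raise ValueError("smiles_raw must be non-empty")


@dataclass(frozen=True)
class Compound:
    """A standardized structure: canonical SMILES, label, heavy-atom count."""

    compound_id: str
    smiles: str
    label: int
    atom_count: int

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


@dataclass(frozen=True)
class Rejection:
    record_id: str
    reason: str
    line: int | None = None


@dataclass
class Dataset:
    """A deduplicated, conflict-free compound collection for one endpoint."""

    endpoint: str
    compounds: list[Compound] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self):
        return iter(self.compounds)

    @property
    def n_positive(self) -> int:
        return sum(c.label for c in self.compounds)

    @property
    def n_negative(self) -> int:
        return len(self.compounds) - self.n_positive

    def labels(self) -> list[int]:
        return [c.label for c in self.compounds]

    def smiles(self) -> list[str]:
        return [c.smiles for c in self.compounds]


def _strip_counterions(mol: Chem.Mol) -> Chem.Mol | None:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    kept = [f for f in frags if Chem.MolToSmiles(f) not in _COUNTERION_SMILES]
    if len(kept) != 1:
        return None
    return kept[0]


def standardize_compound(
    smiles_raw: str,
    label: int = 0,
    compound_id: str = "",
    strip_salts: bool = False,
) -> Compound | Rejection:
    """Standardize a raw SMILES into a canonical :class:`Compound`.

    Never raises for bad structures; failures come back as a
    :class:`Rejection` with one of the typed reasons.  Idempotent on its
    own output: standardizing an accepted canonical SMILES returns the
    same SMILES.

    Gates, in order: parseability; single connected component (salts and
    mixtures share the ``salt_or_multicomponent`` gate — with
    ``strip_salts`` a multi-component entry whose extra pieces are all
    known counterions is reduced to its organic component instead);
    at least one carbon (else ``inorganic``); no metal atoms (else
    ``organometallic``).
    """
    if not smiles_raw or not smiles_raw.strip():
        return Rejection(compound_id, UNPARSEABLE)
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        return Rejection(compound_id, UNPARSEABLE)
    if len(Chem.GetMolFrags(mol)) > 1:
        if strip_salts:
            stripped = _strip_counterions(mol)
            if stripped is None:
                return Rejection(compound_id, SALT_OR_MULTICOMPONENT)
            mol = Chem.MolFromSmiles(Chem.MolToSmiles(stripped))
            if mol is None:
                return Rejection(compound_id, SALT_OR_MULTICOMPONENT)
        else:
            return Rejection(compound_id, SALT_OR_MULTICOMPONENT)
    atoms = list(mol.GetAtoms())
    if not any(a.GetAtomicNum() == 6 for a in atoms):
        return Rejection(compound_id, INORGANIC)
    if any(a.GetAtomicNum() not in _NONMETALS for a in atoms):
        return Rejection(compound_id, ORGANOMETALLIC)
    canonical = Chem.MolToSmiles(mol)
    return Compound(
        compound_id=compound_id,
        smiles=canonical,
        label=label,
        atom_count=mol.GetNumHeavyAtoms(),
    )


def build_dataset(
    records: Iterable[CompoundRecord],
    endpoint: str,
    strip_salts: bool = False,
) -> tuple[Dataset, list[Rejection]]:
    """Standardize, deduplicate, and conflict-filter records into a Dataset.

    Identical-label duplicates collapse to the first-seen record (the
    dropped copies are logged as ``duplicate``); canonical structures
    carrying both labels are removed entirely, each member logged as
    ``label_conflict``.  Output is ordered lexicographically by canonical
    SMILES, so the result is independent of input order.

    Raises :class:`DatasetError` if nothing survives.
    """
    rejections: list[Rejection] = []
    by_smiles: dict[str, list[tuple[CompoundRecord, Compound]]] = {}
    for rec in records:
        result = standardize_compound(
            rec.smiles_raw, label=rec.label,
            compound_id=rec.record_id, strip_salts=strip_salts,
        )
        if isinstance(result, Rejection):
            rejections.append(result)
            continue
        by_smiles.setdefault(result.smiles, []).append((rec, result))

    accepted: list[Compound] = []
    for smiles in sorted(by_smiles):
        group = by_smiles[smiles]
        labels = {rec.label for rec, _ in group}
        if len(labels) > 1:
            rejections.extend(
                Rejection(rec.record_id, LABEL_CONFLICT) for rec, _ in group
            )
            continue
        keep_rec, keep_cmp = group[0]
        accepted.append(keep_cmp)
        rejections.extend(
            Rejection(rec.record_id, DUPLICATE) for rec, _ in group[1:]
        )
    if not accepted:
        raise DatasetError(f"empty dataset for endpoint {endpoint!r}")
    return Dataset(endpoint=endpoint, compounds=accepted), rejections


@dataclass(frozen=True)
class MalformedLine:
    line: int
    content: str
    problem: str


def read_dataset_file(
    path: str | Path,
    fmt: str | None = None,
    default_label: int | None = None,
    endpoint: str = "",
) -> tuple[list[CompoundRecord], list[MalformedLine]]:
    """Read compound records from a ``.csv`` or ``.smi`` file.

    CSV needs a header with at least ``smiles`` and ``label`` columns
    (``id`` and ``endpoint`` optional).  ``.smi`` lines are
    whitespace-delimited ``SMILES [id [label]]``; when a line has no
    label column, ``default_label`` is used (a line with neither is
    malformed).  Records come back in file order; malformed lines are
    reported with line numbers, never silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileFormatError(f"file not found: {path}")
    if fmt is None:
        fmt = "smi" if path.suffix.lower() in (".smi", ".smiles") else "csv"
    if fmt == "csv":
        return _read_csv(path, endpoint)
    if fmt == "smi":
        return _read_smi(path, default_label, endpoint)
    raise FileFormatError(f"unknown format {fmt!r} (expected 'smi' or 'csv')")


def _parse_label(text: str) -> int | None:
    text = text.strip()
    if text in ("0", "1"):
        return int(text)
    return None


def _read_csv(path: Path, endpoint: str):
    records, problems = [], []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FileFormatError(f"{path}: empty file, header required")
        cols = [c.strip().lower() for c in reader.fieldnames]
        for required in ("smiles", "label"):
            if required not in cols:
                raise FileFormatError(f"{path}: missing required column {required!r}")
        for i, row in enumerate(reader, start=2):
            row = {k.strip().lower(): (v or "") for k, v in row.items() if k}
            smiles = row.get("smiles", "").strip()
            label = _parse_label(row.get("label", ""))
            if not smiles:
                problems.append(MalformedLine(i, str(row), "empty smiles"))
                continue
            if label is None:
                problems.append(
                    MalformedLine(i, str(row), f"label {row.get('label')!r} not in {{0,1}}")
                )
                continue
            rec_id = row.get("id", "").strip() or f"row{i}"
            records.append(
                CompoundRecord(rec_id, smiles, label,
                               row.get("endpoint", "").strip() or endpoint)
            )
    return records, problems


def _read_smi(path: Path, default_label: int | None, endpoint: str):
    records, problems = [], []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            rec_id = parts[1] if len(parts) > 1 else f"line{i}"
            if len(parts) > 2:
                label = _parse_label(parts[2])
                if label is None:
                    problems.append(
                        MalformedLine(i, line, f"label {parts[2]!r} not in {{0,1}}")
                    )
                    continue
            elif default_label is not None:
                label = default_label
            else:
                problems.append(MalformedLine(i, line, "no label column and no default label"))
                continue
            records.append(CompoundRecord(rec_id, smiles, label, endpoint))
    return records, problems


def write_dataset_csv(dataset: Dataset, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "smiles", "label", "endpoint"])
        for c in dataset:
            w.writerow([c.compound_id, c.smiles, c.label, dataset.endpoint])


def write_rejections_csv(rejections: Sequence[Rejection], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id", "reason", "line"])
        for r in rejections:
            w.writerow([r.record_id, r.reason, "" if r.line is None else r.line])


def dataset_from_smiles(
    smiles: Iterable[str],
    labels: Iterable[int],
    endpoint: str = "",
    ids: Iterable[str] | None = None,
) -> tuple[Dataset, list[Rejection]]:
    """Convenience: build a Dataset directly from parallel SMILES/label lists."""
    smiles = list(smiles)
    labels = list(labels)
    if len(smiles) != len(labels):
        raise ValueError("smiles and labels must have equal length")
    if ids is None:
        ids = [f"c{i:04d}" for i in range(len(smiles))]
    records = [
        CompoundRecord(rid, s, int(l), endpoint)
        for rid, s, l in zip(ids, smiles, labels)
    ]
    return build_dataset(records, endpoint)
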