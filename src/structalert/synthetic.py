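"""Seeded synthetic endpoint datasets with planted structural alerts.

Real curated endpoint datasets are large and not redistributable, so the
test bed builds its own: compounds are assembled from a fixed library of
small organic scaffolds and benign substituents, a chosen fraction of
them get a *planted* alert fragment embedded, and labels are assigned so
each planted fragment's positive rate hits a target.  Decoy fragments
are embedded at the background label prior, so a correct miner must keep
the planted patterns and reject the decoys.  Everything is driven by one
integer seed; the same spec yields byte-identical datasets.

The manifest that accompanies every dataset records, per pattern, both
the planned and the *realized* support and positive rate (realized =
recomputed by brute-force matching over the emitted compounds), so tests
assert against what was actually generated, not what was asked for.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

from rdkit import Chem

from .catalog import SubstructureCatalog
from .chem import (
    Compound,
    CompoundRecord,
    Dataset,
    build_dataset,
    write_dataset_csv,
)
from .matching import compile_smarts, has_match
from .mining import f_score, mine_fp_filter

# Assembly libraries: simple, valid organics only; no random string synthesis.
SCAFFOLDS: tuple[str, ...] = (
    "C1CCCCC1", "C1CCCC1", "C1CCCCCC1", "c1ccccc1", "c1ccncc1",
    "C1CCOC1", "C1CCOCC1", "C1CCNC1", "C1CCNCC1", "C1CSCC1",
    "CCCCC", "CCCCCC", "CCCCCCC", "CC(C)CC", "CC(C)(C)C",
    "CCOCC", "CCNCC", "CCSCC", "CCOC(C)C", "CCC(C)CC",
)
SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "O", "OC", "F", "Cl", "N", "N(C)C",
    "C(C)=O", "C(=O)O", "SC", "C#N", "c1ccccc1",
)

_MAX_ASSEMBLY_TRIES = 400


class InfeasibleSpecError(ValueError):
    """Raised when a fixture spec cannot be realized at integer counts."""


@dataclass(frozen=True)
class PlantedAlert:
    """A fragment to embed: its pattern doubles as the mining query."""

    pattern: str
    support_fraction: float
    target_pr: float


@dataclass
class FixtureSpec:
    seed: int
    n_compounds: int
    planted_alerts: list[PlantedAlert] = field(default_factory=list)
    decoys: list[str] = field(default_factory=list)
    label_noise: float = 0.0
    endpoint: str = "synthetic"
    background_positive_fraction: float = 0.4
    decoy_support_fraction: float = 0.15

    def __post_init__(self):
        self.planted_alerts = [
            p if isinstance(p, PlantedAlert) else PlantedAlert(*p)
            for p in self.planted_alerts
        ]
        if not 0 <= self.label_noise <= 0.3:
            raise ValueError("label_noise must be in [0, 0.3]")
        for p in self.planted_alerts:
            if not (0 <= p.support_fraction <= 1 and 0 <= p.target_pr <= 1):
                raise ValueError("planted fractions must be in [0, 1]")


def _mol(smiles: str) -> Chem.Mol:
    m = Chem.MolFromSmiles(smiles)
    if m is None:
        raise ValueError(f"library/spec SMILES does not parse: {smiles!r}")
    return m


def _attachable_atoms(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx() for a in mol.GetAtoms()
        if a.GetTotalNumHs() > 0 and a.GetAtomicNum() in (6, 7, 8, 16)
    ]


def _attach(core: Chem.Mol, frag: Chem.Mol, core_atom: int) -> Chem.Mol | None:
    """Join frag to core by a single bond at core_atom and frag's first open atom."""
    # Bracket atoms (e.g. the N of a nitro group) report zero implicit Hs
    # even when they can accept one more bond; fall back to atom 0 and let
    # sanitization reject genuinely impossible attachments.
    frag_sites = _attachable_atoms(frag) or [0]
    combo = Chem.RWMol(Chem.CombineMols(core, frag))
    combo.AddBond(core_atom, core.GetNumAtoms() + frag_sites[0],
                  Chem.BondType.SINGLE)
    try:
        mol = combo.GetMol()
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _decorate(core: Chem.Mol, rng: random.Random, n_subs: int) -> Chem.Mol | None:
    mol = core
    for _ in range(n_subs):
        sites = _attachable_atoms(mol)
        if not sites:
            break
        sub = _mol(SUBSTITUENTS[rng.randrange(len(SUBSTITUENTS))])
        attached = _attach(mol, sub, sites[rng.randrange(len(sites))])
        if attached is not None:
            mol = attached
    return mol


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _plan_counts(spec: FixtureSpec) -> tuple[list[tuple[int, int]], list[int], int]:
    """Integer carrier/positive counts per planted alert, decoy counts, background."""
    n = spec.n_compounds
    planted_counts: list[tuple[int, int]] = []
    for p in spec.planted_alerts:
        carriers = math.ceil(p.support_fraction * n)
        if carriers == 0:
            raise InfeasibleSpecError(
                f"planted {p.pattern!r}: support fraction {p.support_fraction} "
                f"yields no carriers at n={n}"
            )
        n_pos = _round_half_up(p.target_pr * carriers)
        realized = Fraction(n_pos, carriers)
        if abs(realized - Fraction(str(p.target_pr))) > Fraction(1, 20):
            raise InfeasibleSpecError(
                f"planted {p.pattern!r}: target PR {p.target_pr} unreachable "
                f"within ±0.05 at {carriers} carriers (closest {float(realized):.3f})"
            )
        planted_counts.append((carriers, n_pos))
    decoy_counts = [
        max(1, math.ceil(spec.decoy_support_fraction * n)) for _ in spec.decoys
    ]
    used = sum(c for c, _ in planted_counts) + sum(decoy_counts)
    if used > n:
        raise InfeasibleSpecError(
            f"planted + decoy carriers ({used}) exceed n_compounds ({n})"
        )
    return planted_counts, decoy_counts, n - used


def _check_non_subsuming(planted: Sequence[PlantedAlert]) -> None:
    mols = [_mol(p.pattern) for p in planted]
    queries = [compile_smarts(p.pattern) for p in planted]
    for i, qi in enumerate(queries):
        for j, mj in enumerate(mols):
            if i != j and has_match(mj, qi):
                raise ValueError(
                    f"planted scaffolds must be mutually non-subsuming: "
                    f"{planted[i].pattern!r} is a substructure of {planted[j].pattern!r}"
                )


def _build_compound(
    rng: random.Random,
    embed: str | None,
    avoid_queries: list[tuple[str, Chem.Mol]],
    require: str | None,
    seen: set[str],
) -> str:
    """Assemble one unique compound; must match `require` and no `avoid` pattern."""
    for _ in range(_MAX_ASSEMBLY_TRIES):
        core = _mol(SCAFFOLDS[rng.randrange(len(SCAFFOLDS))])
        if embed is not None:
            sites = _attachable_atoms(core)
            attached = _attach(core, _mol(embed), sites[rng.randrange(len(sites))])
            if attached is None:
                continue
            core = attached
        mol = _decorate(core, rng, rng.randrange(0, 3))
        if mol is None:
            continue
        smiles = Chem.MolToSmiles(mol)
        if smiles in seen:
            continue
        mol = Chem.MolFromSmiles(smiles)
        if require is not None and not has_match(mol, compile_smarts(require)):
            continue
        if any(has_match(mol, q) for pat, q in avoid_queries if pat != require):
            continue
        seen.add(smiles)
        return smiles
    raise InfeasibleSpecError(
        f"could not assemble a unique compound (embed={embed!r}) after "
        f"{_MAX_ASSEMBLY_TRIES} attempts; spec patterns may conflict with the "
        "scaffold library"
    )


def generate_dataset(spec: FixtureSpec) -> tuple[Dataset, dict]:
    """Generate a labeled dataset with planted alerts plus its ground truth.

    Fully deterministic given ``spec.seed``.  Raises
    :class:`InfeasibleSpecError` when integer counts cannot realize the
    requested supports/PRs (tolerance ±0.05 on PR).
    """
    _check_non_subsuming(spec.planted_alerts)
    planted_counts, decoy_counts, n_background = _plan_counts(spec)
    rng = random.Random(spec.seed)
    all_patterns = [p.pattern for p in spec.planted_alerts] + list(spec.decoys)
    avoid = [(pat, compile_smarts(pat)) for pat in all_patterns]
    seen: set[str] = set()
    entries: list[tuple[str, int, str | None]] = []  # (smiles, label, planted pattern)

    for p, (carriers, n_pos) in zip(spec.planted_alerts, planted_counts):
        labels = [1] * n_pos + [0] * (carriers - n_pos)
        rng.shuffle(labels)
        for lab in labels:
            smiles = _build_compound(rng, p.pattern, avoid, p.pattern, seen)
            entries.append((smiles, lab, p.pattern))
    prior = spec.background_positive_fraction
    for decoy, carriers in zip(spec.decoys, decoy_counts):
        n_pos = _round_half_up(prior * carriers)
        labels = [1] * n_pos + [0] * (carriers - n_pos)
        rng.shuffle(labels)
        for lab in labels:
            smiles = _build_compound(rng, decoy, avoid, decoy, seen)
            entries.append((smiles, lab, None))
    n_pos = _round_half_up(prior * n_background)
    labels = [1] * n_pos + [0] * (n_background - n_pos)
    rng.shuffle(labels)
    for lab in labels:
        smiles = _build_compound(rng, None, avoid, None, seen)
        entries.append((smiles, lab, None))

    noisy: list[tuple[str, int, int, str | None]] = []
    for smiles, lab, planted in entries:
        final = lab
        if spec.label_noise > 0 and rng.random() < spec.label_noise:
            final = 1 - lab
        noisy.append((smiles, lab, final, planted))

    records = [
        CompoundRecord(f"syn{i:04d}", smiles, final, spec.endpoint)
        for i, (smiles, _, final, _) in enumerate(noisy)
    ]
    dataset, rejections = build_dataset(records, spec.endpoint)
    assert not rejections, "generator produced a rejected compound"
    assert len(dataset) == spec.n_compounds

    manifest = _build_manifest(spec, dataset, noisy)
    return dataset, manifest


def _realized_stats(dataset: Dataset, pattern: str) -> dict:
    query = compile_smarts(pattern)
    presence = [1 if has_match(c.mol(), query) else 0 for c in dataset]
    support = sum(presence)
    n_pos = sum(p for p, c in zip(presence, dataset) if c.label == 1)
    stats = {
        "pattern": pattern,
        "realized_support": support,
        "realized_positive": n_pos,
        "realized_pr": None if support == 0 else n_pos / support,
    }
    if 0 < support and dataset.n_positive and dataset.n_negative:
        stats["realized_f_score"] = f_score(presence, dataset.labels())
    return stats


def _build_manifest(spec: FixtureSpec, dataset: Dataset, noisy) -> dict:
    by_smiles = {smiles: (pre, final, planted) for smiles, pre, final, planted in noisy}
    compounds = []
    for c in dataset:
        pre, final, planted = by_smiles[c.smiles]
        carried = [
            p.pattern for p in spec.planted_alerts
            if has_match(c.mol(), compile_smarts(p.pattern))
        ]
        compounds.append({
            "compound_id": c.compound_id,
            "smiles": c.smiles,
            "label": final,
            "label_pre_noise": pre,
            "planted": carried,
        })
    planted_stats = []
    for p in spec.planted_alerts:
        s = _realized_stats(dataset, p.pattern)
        s.update(target_support_fraction=p.support_fraction, target_pr=p.target_pr)
        planted_stats.append(s)
    return {
        "spec": {
            "seed": spec.seed,
            "n_compounds": spec.n_compounds,
            "endpoint": spec.endpoint,
            "label_noise": spec.label_noise,
            "background_positive_fraction": spec.background_positive_fraction,
        },
        "planted_alerts": planted_stats,
        "decoys": [_realized_stats(dataset, d) for d in spec.decoys],
        "compounds": compounds,
        "pr_tolerance": 0.05,
    }


def write_fixture(dataset: Dataset, manifest: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_dataset_csv(dataset, outdir / "dataset.csv")
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def recovery_experiment(
    spec: FixtureSpec,
    min_support: int = 6,
    min_f: float = 0.005,
    min_pr: float = 0.65,
) -> dict:
    """Generate a fixture, mine it, and report planted/decoy recovery.

    The mining catalog contains exactly the planted and decoy patterns.
    A planted alert is *expected* when its realized support, PR, and
    f-score clear the thresholds; the report gives per-pattern
    recovered/missed status plus the decoy false-alert count (decoys
    with realized PR < 0.5 that were nonetheless emitted).
    """
    dataset, manifest = generate_dataset(spec)
    patterns = [p.pattern for p in spec.planted_alerts] + list(spec.decoys)
    catalog = SubstructureCatalog.from_smarts(patterns, name="recovery")
    alert_set = mine_fp_filter(
        dataset, catalog, min_support=min_support, min_f=min_f, min_pr=min_pr
    )
    mined = set(alert_set.smarts_list())
    min_pr_frac = Fraction(str(min_pr))

    planted_report = []
    for stats in manifest["planted_alerts"]:
        support = stats["realized_support"]
        expected = (
            support >= min_support
            and Fraction(stats["realized_positive"], support) >= min_pr_frac
            and stats.get("realized_f_score", 0.0) >= min_f
        )
        planted_report.append({
            **stats,
            "expected": expected,
            "recovered": stats["pattern"] in mined,
        })
    decoy_report = [
        {**stats, "emitted": stats["pattern"] in mined}
        for stats in manifest["decoys"]
    ]
    expected = [p for p in planted_report if p["expected"]]
    n_recovered = sum(p["recovered"] for p in expected)
    n_false = sum(
        d["emitted"] for d in decoy_report
        if d["realized_pr"] is not None and d["realized_pr"] < 0.5
    )
    return {
        "planted": planted_report,
        "decoys": decoy_report,
        "n_expected": len(expected),
        "n_recovered": n_recovered,
        "recovery_rate": None if not expected else n_recovered / len(expected),
        "n_false_decoy_alerts": n_false,
        "n_alerts_total": len(alert_set),
    }
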