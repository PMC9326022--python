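"""Structural-alert mining: substructure scoring, thresholding, alert sets.

Two mining branches are provided, both frequency-based.  The
fingerprints filter scans a predefined substructure catalog and keeps
keys that occur in enough compounds (support ≥ 6), are enriched in the
toxic class (positive rate ≥ 0.65), and discriminate the classes
(Fisher feature score ≥ 0.005).  The SARpy-style branch enumerates all
fragments of every training compound by acyclic single-bond cleavage
(2–18 heavy atoms, support ≥ 3 parents) and keeps fragments with
positive rate ≥ 0.65, pruning a fragment when a kept, more general
sub-fragment is at least as predictive.

The positive rate of a substructure is
``PR = N_fragment_positive / N_fragment`` where ``N_fragment`` counts
the dataset compounds containing it and ``N_fragment_positive`` the
toxic ones among them.  Threshold comparisons on PR are done in exact
rational arithmetic, so a substructure at exactly the 0.65 boundary is
retained.

Alert sets are deduplicated by SMARTS and deterministically ordered
(descending PR, then descending support, then lexicographic SMARTS);
two runs on the same inputs produce byte-identical JSON files.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Sequence

from rdkit import Chem

from .catalog import SubstructureCatalog
from .chem import Dataset
from .fragments import (
    DEFAULT_FRAGMENT_CAP,
    DEFAULT_MAX_ATOMS,
    DEFAULT_MIN_ATOMS,
    Fragment,
    enumerate_fragments,
    fragment_support,
)
from .matching import compile_smarts, has_match

#: Score assigned to a perfect separator whose within-class variances vanish.
F_SCORE_SENTINEL = 1e9

ORIGIN_FP_FILTER = "fp_filter"
ORIGIN_SARPY = "sarpy"
ORIGIN_IMPORTED = "imported"
_ORIGIN_PRIORITY = {ORIGIN_FP_FILTER: 0, ORIGIN_SARPY: 1, ORIGIN_IMPORTED: 2}


class MiningError(ValueError):
    """Raised for unusable mining inputs (e.g. single-class dataset)."""


class AlertSetSchemaError(ValueError):
    """Raised when an alert-set file violates the JSON schema."""


@dataclass(frozen=True)
class FragmentStats:
    """Support and enrichment of one substructure against one dataset."""

    n_fragment: int
    n_fragment_positive: int
    pr: float
    f_score: float | None = None

    def __post_init__(self):
        if not 0 <= self.n_fragment_positive <= self.n_fragment:
            raise ValueError("need 0 <= n_fragment_positive <= n_fragment")


@dataclass(frozen=True)
class StructuralAlert:
    alert_id: str
    smarts: str
    endpoint: str
    origin: str
    stats: FragmentStats | None = None


@dataclass
class AlertSet:
    """A deduplicated, deterministically ordered alert collection."""

    endpoint: str
    alerts: list[StructuralAlert] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.alerts)

    def __iter__(self):
        return iter(self.alerts)

    def smarts_list(self) -> list[str]:
        return [a.smarts for a in self.alerts]


def positive_rate(n_fragment_positive: int, n_fragment: int) -> float:
    """PR = N_fragment_positive / N_fragment (undefined for zero carriers)."""
    if n_fragment < 1:
        raise MiningError("positive rate undefined: fragment occurs in no compound")
    if not 0 <= n_fragment_positive <= n_fragment:
        raise ValueError("need 0 <= n_fragment_positive <= n_fragment")
    return n_fragment_positive / n_fragment


def f_score(presence: Sequence[int], labels: Sequence[int]) -> float:
    """Fisher feature-selection score of a binary presence feature.

    ``F = ((m+ − m)² + (m− − m)²) / (v+ + v−)`` where m+/m−/m are the
    feature means over positives/negatives/all compounds and v+/v− the
    within-class sample variances (ddof 1; a class of size 1 contributes
    zero variance).  A feature constant over the whole dataset scores 0;
    a perfect separator with zero within-class variance scores the
    serializable sentinel ``F_SCORE_SENTINEL``.  Computed in exact
    rational arithmetic and converted to float at the end.
    """
    presence = list(presence)
    labels = list(labels)
    if len(presence) != len(labels):
        raise ValueError("presence and labels must have equal length")
    if len(presence) < 2:
        raise ValueError("need at least 2 compounds")
    if set(labels) != {0, 1}:
        raise MiningError("f_score requires both classes in labels")
    pos = [p for p, y in zip(presence, labels) if y == 1]
    neg = [p for p, y in zip(presence, labels) if y == 0]
    n_pos, n_neg, n = len(pos), len(neg), len(presence)
    a, b = sum(pos), sum(neg)
    m_pos = Fraction(a, n_pos)
    m_neg = Fraction(b, n_neg)
    m_all = Fraction(a + b, n)

    def _sample_var(k: int, size: int, mean: Fraction) -> Fraction:
        if size <= 1:
            return Fraction(0)
        ssd = k * (1 - mean) ** 2 + (size - k) * mean ** 2
        return ssd / (size - 1)

    v_pos = _sample_var(a, n_pos, m_pos)
    v_neg = _sample_var(b, n_neg, m_neg)
    numer = (m_pos - m_all) ** 2 + (m_neg - m_all) ** 2
    denom = v_pos + v_neg
    if denom == 0:
        return 0.0 if numer == 0 else F_SCORE_SENTINEL
    return float(numer / denom)


def _carriers(dataset: Dataset, query: Chem.Mol) -> tuple[frozenset[str], int]:
    """(carrier compound ids, positive carrier count) for one query."""
    ids, n_pos = [], 0
    for compound in dataset:
        if has_match(compound.mol(), query):
            ids.append(compound.compound_id)
            n_pos += compound.label
    return frozenset(ids), n_pos


def _require_two_classes(dataset: Dataset) -> None:
    if dataset.n_positive == 0 or dataset.n_negative == 0:
        raise MiningError(
            f"dataset for endpoint {dataset.endpoint!r} has a single class "
            f"({dataset.n_positive} positive / {dataset.n_negative} negative)"
        )


def _slug(text: str) -> str:
    slug = re.sub(r"[^a-z0-9]+", "-", text.lower()).strip("-")
    return slug or "endpoint"


def _sort_key(alert: StructuralAlert):
    pr = alert.stats.pr if alert.stats else -1.0
    nf = alert.stats.n_fragment if alert.stats else -1
    return (-pr, -nf, alert.smarts)


def _finalize(endpoint: str, origin: str,
              scored: list[tuple[str, FragmentStats]],
              provenance: dict) -> AlertSet:
    """Order deterministically and assign stable human-readable ids."""
    alerts = [
        StructuralAlert(alert_id="", smarts=s, endpoint=endpoint,
                        origin=origin, stats=st)
        for s, st in scored
    ]
    alerts.sort(key=_sort_key)
    slug = _slug(endpoint)
    alerts = [
        replace(a, alert_id=f"{slug}_{origin}_{i:04d}")
        for i, a in enumerate(alerts)
    ]
    return AlertSet(endpoint=endpoint, alerts=alerts, provenance=provenance)


def mine_fp_filter(
    dataset: Dataset,
    catalog: SubstructureCatalog,
    min_support: int = 6,
    min_f: float = 0.005,
    min_pr: float = 0.65,
) -> AlertSet:
    """Mine alerts by scanning a predefined substructure catalog.

    A catalog key becomes an alert iff it occurs in ≥ ``min_support``
    compounds, its Fisher feature score is ≥ ``min_f``, and its positive
    rate is ≥ ``min_pr`` (all thresholds inclusive; the PR comparison is
    exact-rational so boundary cases are retained).
    """
    _require_two_classes(dataset)
    labels = dataset.labels()
    min_pr_frac = Fraction(str(min_pr))
    scored: list[tuple[str, FragmentStats]] = []
    seen: set[str] = set()
    for entry, query in zip(catalog.entries, catalog.queries()):
        if entry.smarts in seen:
            continue
        seen.add(entry.smarts)
        presence = [1 if has_match(c.mol(), query) else 0 for c in dataset]
        n_frag = sum(presence)
        if n_frag < min_support:
            continue
        n_pos = sum(p for p, y in zip(presence, labels) if y == 1)
        if Fraction(n_pos, n_frag) < min_pr_frac:
            continue
        f = f_score(presence, labels)
        if f < min_f:
            continue
        stats = FragmentStats(n_frag, n_pos, positive_rate(n_pos, n_frag), f)
        scored.append((entry.smarts, stats))
    provenance = {
        "method": ORIGIN_FP_FILTER,
        "catalog": catalog.name,
        "catalog_size": len(catalog),
        "min_support": min_support,
        "min_f": min_f,
        "min_pr": min_pr,
        "n_compounds": len(dataset),
        "n_positive": dataset.n_positive,
    }
    return _finalize(dataset.endpoint, ORIGIN_FP_FILTER, scored, provenance)


def _pattern_as_mol(pattern: str) -> Chem.Mol | None:
    """Parse a fragment pattern as a molecule for containment checks.

    Fragment patterns can carry valence states that full sanitization
    rejects (e.g. an aromatic nitrogen cut free of its substituent), so
    sanitization is skipped and only the property cache and ring info
    needed for matching are rebuilt.
    """
    mol = Chem.MolFromSmiles(pattern, sanitize=False)
    if mol is None:
        return None
    try:
        mol.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(mol)
    except Exception:
        return None
    return mol


def _prune_dominated(
    candidates: list[tuple[Fragment, frozenset[str], int]],
) -> tuple[list[tuple[Fragment, frozenset[str], int]], list[str]]:
    """Drop fragments dominated by a kept, more general sub-fragment.

    Candidates are decided smallest-first; a fragment is dropped when a
    kept smaller fragment carries a superset of its compounds with PR at
    least as high and is structurally contained in it (contained-in
    check falls back to the carrier-set evidence when the larger pattern
    cannot be re-parsed).
    """
    ordered = sorted(candidates, key=lambda t: (t[0].atom_count, t[0].pattern))
    kept: list[tuple[Fragment, frozenset[str], int]] = []
    pruned: list[str] = []
    for frag, carriers, n_pos in ordered:
        pr = Fraction(n_pos, len(carriers))
        dominated = False
        for kfrag, kcarriers, kn_pos in kept:
            if kfrag.atom_count >= frag.atom_count:
                continue
            if not carriers <= kcarriers:
                continue
            if Fraction(kn_pos, len(kcarriers)) < pr:
                continue
            outer = _pattern_as_mol(frag.pattern)
            if outer is None or has_match(outer, kfrag.to_query()):
                dominated = True
                break
        if dominated:
            pruned.append(frag.pattern)
        else:
            kept.append((frag, carriers, n_pos))
    return kept, pruned


def mine_sarpy(
    dataset: Dataset,
    min_atoms: int = DEFAULT_MIN_ATOMS,
    max_atoms: int = DEFAULT_MAX_ATOMS,
    min_support: int = 3,
    min_pr: float = 0.65,
    prune_dominated: bool = True,
    fragment_cap: int = DEFAULT_FRAGMENT_CAP,
) -> AlertSet:
    """Mine alerts by exhaustive fragment enumeration and frequency analysis.

    Every compound is cleaved into all fragments of ``min_atoms`` to
    ``max_atoms`` heavy atoms; fragments found in ≥ ``min_support``
    compounds are scored by positive rate over the whole dataset via
    SMARTS matching, and those with PR ≥ ``min_pr`` are kept.  With
    ``prune_dominated`` a kept fragment subsumed by an equally or more
    predictive sub-fragment is dropped, keeping the rule set minimal.
    """
    _require_two_classes(dataset)
    frags_by_compound = {
        c.compound_id: enumerate_fragments(
            c, min_atoms=min_atoms, max_atoms=max_atoms, fragment_cap=fragment_cap
        )
        for c in dataset
    }
    supported = fragment_support(frags_by_compound, dataset, min_support=min_support)
    min_pr_frac = Fraction(str(min_pr))
    candidates: list[tuple[Fragment, frozenset[str], int]] = []
    for frag in supported:
        carriers, n_pos = _carriers(dataset, frag.to_query())
        if len(carriers) < min_support:
            continue
        if Fraction(n_pos, len(carriers)) < min_pr_frac:
            continue
        candidates.append((Fragment(frag.pattern, frag.atom_count, carriers),
                           carriers, n_pos))
    n_pruned = 0
    if prune_dominated:
        candidates, pruned = _prune_dominated(candidates)
        n_pruned = len(pruned)
    scored = [
        (frag.pattern,
         FragmentStats(len(carriers), n_pos,
                       positive_rate(n_pos, len(carriers)), None))
        for frag, carriers, n_pos in candidates
    ]
    provenance = {
        "method": ORIGIN_SARPY,
        "min_atoms": min_atoms,
        "max_atoms": max_atoms,
        "min_support": min_support,
        "min_pr": min_pr,
        "prune_dominated": prune_dominated,
        "n_pruned_dominated": n_pruned,
        "n_compounds": len(dataset),
        "n_positive": dataset.n_positive,
    }
    return _finalize(dataset.endpoint, ORIGIN_SARPY, scored, provenance)


def merge_alert_sets(sets: Sequence[AlertSet]) -> AlertSet:
    """Union alert sets for one endpoint, removing SMARTS duplicates.

    On a duplicate SMARTS the entry with the larger support wins; ties
    break by origin (fp_filter > sarpy > imported).  The result is
    re-ordered and re-identified deterministically, so the merge is
    insensitive to input order up to the stated tie rule.
    """
    if not sets:
        raise ValueError("nothing to merge")
    endpoints = {s.endpoint for s in sets}
    if len(endpoints) > 1:
        raise MiningError(f"cannot merge alert sets across endpoints: {sorted(endpoints)}")
    endpoint = sets[0].endpoint
    best: dict[str, StructuralAlert] = {}
    for aset in sets:
        for alert in aset:
            rank = (
                alert.stats.n_fragment if alert.stats else -1,
                -_ORIGIN_PRIORITY.get(alert.origin, 99),
            )
            prev = best.get(alert.smarts)
            if prev is None:
                best[alert.smarts] = alert
                continue
            prev_rank = (
                prev.stats.n_fragment if prev.stats else -1,
                -_ORIGIN_PRIORITY.get(prev.origin, 99),
            )
            if rank > prev_rank:
                best[alert.smarts] = alert
    alerts = sorted(best.values(), key=_sort_key)
    slug = _slug(endpoint)
    alerts = [
        replace(a, alert_id=f"{slug}_merged_{i:04d}") for i, a in enumerate(alerts)
    ]
    provenance = {
        "method": "merge",
        "sources": [s.provenance.get("method", "unknown") for s in sets],
        "n_sources": len(sets),
    }
    return AlertSet(endpoint=endpoint, alerts=alerts, provenance=provenance)


# --- serialization ---------------------------------------------------------

def _alert_to_json(alert: StructuralAlert) -> dict:
    d = {
        "alert_id": alert.alert_id,
        "smarts": alert.smarts,
        "origin": alert.origin,
    }
    if alert.stats is not None:
        d.update(
            n_fragment=alert.stats.n_fragment,
            n_fragment_positive=alert.stats.n_fragment_positive,
            pr=alert.stats.pr,
            f_score=alert.stats.f_score,
        )
    return d


def save_alert_set(alert_set: AlertSet, path: str | Path) -> None:
    """Write an alert set as deterministic JSON (sorted keys, 2-space indent)."""
    doc = {
        "endpoint": alert_set.endpoint,
        "provenance": alert_set.provenance,
        "alerts": [_alert_to_json(a) for a in alert_set.alerts],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_alert_set(path: str | Path) -> AlertSet:
    """Load an alert-set JSON file, validating the schema.

    Schema violations raise :class:`AlertSetSchemaError` naming the JSON
    path of the offending field.
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict):
        raise AlertSetSchemaError("$: expected an object")
    for key in ("endpoint", "alerts"):
        if key not in doc:
            raise AlertSetSchemaError(f"$.{key}: missing required field")
    alerts = []
    for i, item in enumerate(doc["alerts"]):
        where = f"$.alerts[{i}]"
        if not isinstance(item, dict):
            raise AlertSetSchemaError(f"{where}: expected an object")
        for key in ("alert_id", "smarts", "origin"):
            if key not in item:
                raise AlertSetSchemaError(f"{where}.{key}: missing required field")
        try:
            compile_smarts(item["smarts"])
        except ValueError as exc:
            raise AlertSetSchemaError(f"{where}.smarts: {exc}") from exc
        stats = None
        if "n_fragment" in item:
            for key in ("n_fragment_positive", "pr"):
                if key not in item:
                    raise AlertSetSchemaError(f"{where}.{key}: missing required field")
            stats = FragmentStats(
                n_fragment=int(item["n_fragment"]),
                n_fragment_positive=int(item["n_fragment_positive"]),
                pr=float(item["pr"]),
                f_score=None if item.get("f_score") is None else float(item["f_score"]),
            )
        alerts.append(
            StructuralAlert(
                alert_id=str(item["alert_id"]),
                smarts=str(item["smarts"]),
                endpoint=str(doc["endpoint"]),
                origin=str(item["origin"]),
                stats=stats,
            )
        )
    return AlertSet(
        endpoint=str(doc["endpoint"]),
        alerts=alerts,
        provenance=doc.get("provenance", {}),
    )


def import_smarts_list(path: str | Path, endpoint: str) -> AlertSet:
    """Import a plain SMARTS-per-line list as an alert set (origin imported)."""
    slug = _slug(endpoint)
    alerts: list[StructuralAlert] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            smarts = line.split("\t")[0].strip()
            compile_smarts(smarts)
            if smarts in seen:
                continue
            seen.add(smarts)
            alerts.append(
                StructuralAlert(alert_id="", smarts=smarts, endpoint=endpoint,
                                origin=ORIGIN_IMPORTED, stats=None)
            )
    alerts.sort(key=_sort_key)
    alerts = [
        replace(a, alert_id=f"{slug}_{ORIGIN_IMPORTED}_{i:04d}")
        for i, a in enumerate(alerts)
    ]
    return AlertSet(endpoint=endpoint, alerts=alerts,
                    provenance={"method": ORIGIN_IMPORTED, "source": str(path)})


def export_smarts_list(alert_set: AlertSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for alert in alert_set:
            fh.write(f"{alert.smarts}\t{alert.alert_id}\n")
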