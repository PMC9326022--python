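"""Query screening against alert sets with applicability-domain flagging.

The prediction rule is the expert-system one: a compound that contains
one or more structural alerts of an endpoint is predicted positive for
that endpoint; otherwise negative.  Each hit is reported with the query
atom indices of every distinct embedding (0-based over the canonical
query structure) so the matched fragment can be highlighted.

The applicability domain is similarity-based: a query is in-domain when
its Tanimoto similarity to at least one training compound, computed on
catalog substructure-key fingerprints, is ≥ the cutoff (0.5 by default,
inclusive).  The flag is advisory — verdicts are reported either way and
callers may gate on it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem

from .catalog import (
    BinaryFingerprint,
    CatalogError,
    SubstructureCatalog,
    compute_fingerprint,
    tanimoto,
)
from .chem import Compound, Dataset, Rejection, standardize_compound
from .matching import compile_smarts, substructure_matches
from .mining import AlertSet, StructuralAlert

DEFAULT_AD_CUTOFF = 0.5


@dataclass(frozen=True)
class AlertMatch:
    """One alert hit: every distinct embedding as a query-atom index list."""

    alert_id: str
    smarts: str
    atom_index_lists: tuple[tuple[int, ...], ...]


@dataclass(frozen=True)
class ScreeningResult:
    query_id: str
    endpoint: str
    verdict: str  # "positive" | "negative"
    matches: tuple[AlertMatch, ...]
    in_domain: bool | None = None
    max_similarity: float | None = None
    nearest_training_id: str | None = None

    @property
    def is_positive(self) -> bool:
        return self.verdict == "positive"


@dataclass
class DomainModel:
    """Similarity applicability domain over a training set's fingerprints."""

    catalog: SubstructureCatalog
    training_fingerprints: list[tuple[str, BinaryFingerprint]]
    cutoff: float = DEFAULT_AD_CUTOFF

    def __post_init__(self):
        if not 0 <= self.cutoff <= 1:
            raise ValueError("cutoff must be in [0, 1]")
        if not self.training_fingerprints:
            raise ValueError("domain model needs a nonempty training set")

    @classmethod
    def from_dataset(
        cls,
        dataset: Dataset,
        catalog: SubstructureCatalog,
        cutoff: float = DEFAULT_AD_CUTOFF,
    ) -> "DomainModel":
        fps = [
            (c.compound_id, compute_fingerprint(c, catalog)) for c in dataset
        ]
        return cls(catalog=catalog, training_fingerprints=fps, cutoff=cutoff)


def in_domain(
    query_fp: BinaryFingerprint, domain: DomainModel
) -> tuple[bool, float, str | None]:
    """(in-domain?, max Tanimoto, nearest training id); cutoff is inclusive."""
    if query_fp.catalog_name != domain.catalog.name:
        raise CatalogError(
            f"query fingerprint catalog {query_fp.catalog_name!r} does not "
            f"match domain catalog {domain.catalog.name!r}"
        )
    best_tc, best_id = 0.0, None
    for cid, fp in domain.training_fingerprints:
        tc = tanimoto(query_fp, fp)
        if tc > best_tc or best_id is None:
            best_tc, best_id = tc, cid
    return best_tc >= domain.cutoff, best_tc, best_id


def match_alert(
    query: Compound | Chem.Mol, alert: StructuralAlert | str
) -> tuple[tuple[int, ...], ...]:
    """All distinct embeddings of an alert in a query, as atom-index tuples.

    Embeddings covering the same atom set collapse to one entry.  An
    empty tuple means no match.  Unparseable SMARTS raise at alert
    compile time, never silently at match time.
    """
    smarts = alert if isinstance(alert, str) else alert.smarts
    query_mol = query.mol() if isinstance(query, Compound) else query
    return substructure_matches(query_mol, compile_smarts(smarts))


def screen(
    query: Compound,
    alert_set: AlertSet,
    domain: DomainModel | None = None,
) -> ScreeningResult:
    """Screen one compound: positive iff ≥ 1 alert matches.

    Matches come back in alert-set order.  When a domain model is given,
    the AD flag and max similarity are attached; the verdict itself is
    never suppressed by the AD.
    """
    mol = query.mol()
    matches = []
    for alert in alert_set:
        embeddings = substructure_matches(mol, compile_smarts(alert.smarts))
        if embeddings:
            matches.append(
                AlertMatch(alert.alert_id, alert.smarts, embeddings)
            )
    in_dom = max_sim = nearest = None
    if domain is not None:
        fp = compute_fingerprint(query, domain.catalog)
        in_dom, max_sim, nearest = in_domain(fp, domain)
    return ScreeningResult(
        query_id=query.compound_id,
        endpoint=alert_set.endpoint,
        verdict="positive" if matches else "negative",
        matches=tuple(matches),
        in_domain=in_dom,
        max_similarity=max_sim,
        nearest_training_id=nearest,
    )


def screen_batch(
    queries: Iterable[tuple[str, str]] | str | Path,
    alert_sets: Sequence[AlertSet],
    domains: Sequence[DomainModel | None] | None = None,
    ad_gate: bool = False,
) -> pd.DataFrame:
    """Screen many queries against many endpoints into a tabular report.

    ``queries`` is an iterable of (query_id, smiles) or a path to a
    ``.smi`` file.  One row per (query, endpoint); an unparseable or
    rejected query yields a single error row instead of aborting the
    batch.  With ``ad_gate`` the verdict of an out-of-domain query is
    replaced by ``no_prediction``.
    """
    if isinstance(queries, (str, Path)):
        queries = _read_query_file(queries)
    else:
        queries = list(queries)
    if domains is None:
        domains = [None] * len(alert_sets)
    if len(domains) != len(alert_sets):
        raise ValueError("domains must align with alert_sets")
    rows = []
    for qid, smiles in queries:
        std = standardize_compound(smiles, compound_id=qid)
        if isinstance(std, Rejection):
            rows.append({
                "query_id": qid, "endpoint": "", "verdict": f"error:{std.reason}",
                "alert_ids": "", "in_domain": "", "max_similarity": "",
                "nearest_training_id": "",
            })
            continue
        for alert_set, domain in zip(alert_sets, domains):
            result = screen(std, alert_set, domain)
            verdict = result.verdict
            if ad_gate and result.in_domain is False:
                verdict = "no_prediction"
            rows.append({
                "query_id": qid,
                "endpoint": alert_set.endpoint,
                "verdict": verdict,
                "alert_ids": ";".join(m.alert_id for m in result.matches),
                "in_domain": "" if result.in_domain is None else result.in_domain,
                "max_similarity": ""
                if result.max_similarity is None
                else round(result.max_similarity, 4),
                "nearest_training_id": result.nearest_training_id or "",
            })
    return pd.DataFrame(
        rows,
        columns=["query_id", "endpoint", "verdict", "alert_ids",
                 "in_domain", "max_similarity", "nearest_training_id"],
    )


def _read_query_file(path: str | Path) -> list[tuple[str, str]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            out.append((parts[1] if len(parts) > 1 else f"query{i}", parts[0]))
    return out


# --- domain-model serialization (self-contained: catalog travels along) ----

def save_domain_model(domain: DomainModel, path: str | Path) -> None:
    doc = {
        "cutoff": domain.cutoff,
        "catalog": {
            "name": domain.catalog.name,
            "smarts": [[e.smarts, e.label] for e in domain.catalog.entries],
        },
        "training_fingerprints": [
            [cid, sorted(fp.bits)] for cid, fp in domain.training_fingerprints
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_domain_model(path: str | Path) -> DomainModel:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    catalog = SubstructureCatalog.from_smarts(
        [tuple(p) for p in doc["catalog"]["smarts"]], name=doc["catalog"]["name"]
    )
    fps = [
        (cid, BinaryFingerprint(catalog.name, frozenset(bits)))
        for cid, bits in doc["training_fingerprints"]
    ]
    return DomainModel(catalog=catalog, training_fingerprints=fps,
                       cutoff=float(doc["cutoff"]))
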