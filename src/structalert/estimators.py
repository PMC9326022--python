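"""Scikit-learn-style estimators wrapping alert mining and screening.

``StructuralAlertClassifier`` treats alert mining as model fitting:
``fit(X, y)`` takes SMILES strings and binary toxicity labels,
standardizes them into a dataset, and mines an alert set (fingerprints
filter or SARpy-style branch); ``predict(X)`` screens queries with the
contains-an-alert rule.  ``TanimotoApplicabilityDomain`` is the
similarity domain as a fitted model with ``predict`` (in/out) and
``score_samples`` (max Tc).  Both follow sklearn conventions
(get_params/set_params, trailing-underscore fitted attributes,
NotFittedError), so they compose with pipelines and model selection.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

from .catalog import SubstructureCatalog, compute_fingerprint, default_catalog
from .chem import Compound, Rejection, dataset_from_smiles, standardize_compound
from .evaluation import MetricsReport, evaluate_alert_set
from .mining import AlertSet, mine_fp_filter, mine_sarpy
from .screening import DomainModel, in_domain, screen


def _as_smiles_list(X) -> list[str]:
    if isinstance(X, str):
        raise ValueError("X must be a sequence of SMILES strings, not one string")
    arr = np.asarray(X, dtype=object)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr.ravel()
    if arr.ndim != 1:
        raise ValueError(f"X must be 1-d (or a single column); got shape {arr.shape}")
    return [str(s) for s in arr]


def _standardize_queries(smiles: Sequence[str]) -> list[Compound]:
    out, bad = [], []
    for i, s in enumerate(smiles):
        std = standardize_compound(s, compound_id=f"q{i}")
        if isinstance(std, Rejection):
            bad.append((i, s, std.reason))
        else:
            out.append(std)
    if bad:
        shown = "; ".join(f"index {i} ({r}): {s!r}" for i, s, r in bad[:5])
        raise ValueError(f"{len(bad)} query structure(s) rejected: {shown}")
    return out


class TanimotoApplicabilityDomain(BaseEstimator):
    """Similarity-based applicability domain on substructure-key fingerprints.

    A query is in-domain when its Tanimoto coefficient to at least one
    training compound is >= ``cutoff`` (inclusive).

    Parameters
    ----------
    catalog : SubstructureCatalog or None
        Substructure-key catalog defining the fingerprint space; the
        bundled toxicophore catalog when None.
    cutoff : float, default 0.5
        Inclusive Tc threshold for domain membership.
    """

    def __init__(self, catalog: SubstructureCatalog | None = None,
                 cutoff: float = 0.5):
        self.catalog = catalog
        self.cutoff = cutoff

    def fit(self, X, y=None):
        smiles = _as_smiles_list(X)
        compounds = _standardize_queries(smiles)
        catalog = self.catalog if self.catalog is not None else default_catalog()
        self.domain_ = DomainModel(
            catalog=catalog,
            training_fingerprints=[
                (c.compound_id, compute_fingerprint(c, catalog)) for c in compounds
            ],
            cutoff=self.cutoff,
        )
        self.n_training_ = len(compounds)
        return self

    def _check_fitted(self):
        if not hasattr(self, "domain_"):
            raise NotFittedError(
                f"{type(self).__name__} is not fitted; call fit first"
            )

    def score_samples(self, X) -> np.ndarray:
        """Max Tanimoto similarity of each query to the training set."""
        self._check_fitted()
        compounds = _standardize_queries(_as_smiles_list(X))
        return np.array([
            in_domain(compute_fingerprint(c, self.domain_.catalog), self.domain_)[1]
            for c in compounds
        ])

    def predict(self, X) -> np.ndarray:
        """Boolean in-domain flag per query (cutoff inclusive)."""
        self._check_fitted()
        return self.score_samples(X) >= self.cutoff


class StructuralAlertClassifier(ClassifierMixin, BaseEstimator):
    """Toxicity classifier backed by a mined structural-alert set.

    Parameters
    ----------
    method : {"fp_filter", "sarpy"}
        Mining branch: catalog scan with support/PR/f-score thresholds,
        or exhaustive fragment enumeration with support/PR thresholds.
    catalog : SubstructureCatalog or None
        Substructure catalog for the fp_filter branch and the AD
        fingerprints; bundled default when None.
    min_support : int or None
        Minimum carrier count; method default when None (6 for
        fp_filter, 3 for sarpy).
    min_pr : float, default 0.65
        Minimum positive rate (inclusive).
    min_f : float, default 0.005
        Minimum Fisher feature score (fp_filter branch only).
    min_atoms, max_atoms : int
        Fragment size window for the sarpy branch (heavy atoms).
    prune_dominated : bool, default True
        Drop sarpy fragments dominated by an equally predictive
        sub-fragment.
    fit_domain : bool, default True
        Also fit a Tanimoto applicability domain on the training set.
    ad_cutoff : float, default 0.5
        Inclusive Tc threshold for the domain.
    endpoint : str
        Endpoint name stamped on the alert set.

    Attributes
    ----------
    alerts_ : AlertSet
        The mined, deduplicated, deterministically ordered alert set.
    domain_ : DomainModel or None
        Fitted applicability domain (when ``fit_domain``).
    classes_ : ndarray of shape (2,)
        Always ``[0, 1]``.
    """

    def __init__(
        self,
        method: str = "fp_filter",
        catalog: SubstructureCatalog | None = None,
        min_support: int | None = None,
        min_pr: float = 0.65,
        min_f: float = 0.005,
        min_atoms: int = 2,
        max_atoms: int = 18,
        prune_dominated: bool = True,
        fit_domain: bool = True,
        ad_cutoff: float = 0.5,
        endpoint: str = "endpoint",
    ):
        self.method = method
        self.catalog = catalog
        self.min_support = min_support
        self.min_pr = min_pr
        self.min_f = min_f
        self.min_atoms = min_atoms
        self.max_atoms = max_atoms
        self.prune_dominated = prune_dominated
        self.fit_domain = fit_domain
        self.ad_cutoff = ad_cutoff
        self.endpoint = endpoint

    def fit(self, X, y):
        smiles = _as_smiles_list(X)
        y = np.asarray(y).ravel()
        if len(y) != len(smiles):
            raise ValueError("X and y must have equal length")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("y must be binary (0 = non-toxic, 1 = toxic)")
        dataset, self.rejections_ = dataset_from_smiles(
            smiles, [int(v) for v in y], endpoint=self.endpoint
        )
        self.dataset_ = dataset
        if self.method == "fp_filter":
            catalog = self._resolve_catalog()
            self.alerts_ = mine_fp_filter(
                dataset, catalog,
                min_support=6 if self.min_support is None else self.min_support,
                min_f=self.min_f, min_pr=self.min_pr,
            )
        elif self.method == "sarpy":
            self.alerts_ = mine_sarpy(
                dataset,
                min_atoms=self.min_atoms, max_atoms=self.max_atoms,
                min_support=3 if self.min_support is None else self.min_support,
                min_pr=self.min_pr, prune_dominated=self.prune_dominated,
            )
        else:
            raise ValueError(
                f"method must be 'fp_filter' or 'sarpy', got {self.method!r}"
            )
        self.domain_ = (
            DomainModel.from_dataset(dataset, self._resolve_catalog(),
                                     cutoff=self.ad_cutoff)
            if self.fit_domain else None
        )
        self.classes_ = np.array([0, 1])
        return self

    def _resolve_catalog(self) -> SubstructureCatalog:
        if not hasattr(self, "_catalog_cache") or self._catalog_cache is None:
            self._catalog_cache = (
                self.catalog if self.catalog is not None else default_catalog()
            )
        return self._catalog_cache

    def _check_fitted(self):
        if not hasattr(self, "alerts_"):
            raise NotFittedError(
                f"{type(self).__name__} is not fitted; call fit first"
            )

    def predict(self, X) -> np.ndarray:
        """1 iff the query contains at least one mined alert."""
        self._check_fitted()
        compounds = _standardize_queries(_as_smiles_list(X))
        return np.array([
            1 if screen(c, self.alerts_).is_positive else 0 for c in compounds
        ])

    def screen(self, X) -> pd.DataFrame:
        """Detailed per-query report: verdict, matched alerts, AD flag."""
        self._check_fitted()
        compounds = _standardize_queries(_as_smiles_list(X))
        rows = []
        for c in compounds:
            r = screen(c, self.alerts_, self.domain_)
            rows.append({
                "query_id": c.compound_id,
                "smiles": c.smiles,
                "verdict": r.verdict,
                "alert_ids": ";".join(m.alert_id for m in r.matches),
                "in_domain": r.in_domain,
                "max_similarity": r.max_similarity,
                "nearest_training_id": r.nearest_training_id,
            })
        return pd.DataFrame(rows)

    def evaluate(self, ad_stratify: bool = False) -> MetricsReport | dict:
        """Resubstitution metrics of the mined alerts on the training set."""
        self._check_fitted()
        return evaluate_alert_set(
            self.dataset_, self.alerts_, self.domain_, ad_stratify=ad_stratify
        )
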