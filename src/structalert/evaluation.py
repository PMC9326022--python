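"""Evaluation of alert sets against labeled datasets.

An alert set is an all-or-nothing classifier — a compound is predicted
toxic iff it carries at least one alert — so its quality is summarized
by the confusion counts and four derived statistics:

    Q   = (TP + TN) / (TP + FN + TN + FP)   total accuracy
    SE  = TP / (TP + FN)                    sensitivity
    SP  = TN / (TN + FP)                    specificity
    PPV = TP / (TP + FP)                    positive predictive value

A statistic whose denominator is zero is *undefined* (rendered "NA"),
never silently 0.  Reports can be stratified by applicability-domain
membership; the stratum counts partition the totals exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .chem import Dataset
from .mining import AlertSet
from .screening import DomainModel, screen


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass(frozen=True)
class MetricsReport:
    counts: ConfusionCounts
    q: float | None
    se: float | None
    sp: float | None
    ppv: float | None
    endpoint: str = ""
    n_alerts: int = 0
    stratum: str = "all"


def confusion(predictions: Sequence[int], labels: Sequence[int]) -> ConfusionCounts:
    """Exact confusion counts of binary predictions against binary labels."""
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must have equal length")
    if len(labels) < 1:
        raise ValueError("need at least one compound")
    tp = fp = tn = fn = 0
    for p, y in zip(predictions, labels):
        if p not in (0, 1) or y not in (0, 1):
            raise ValueError("predictions and labels must be binary")
        if p and y:
            tp += 1
        elif p and not y:
            fp += 1
        elif not p and not y:
            tn += 1
        else:
            fn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def metrics(
    counts: ConfusionCounts, endpoint: str = "", n_alerts: int = 0,
    stratum: str = "all",
) -> MetricsReport:
    """Q, SE, SP, PPV from confusion counts; zero denominators ⇒ undefined."""
    if counts.total < 1:
        raise ValueError("need at least one evaluated compound")

    def _ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    return MetricsReport(
        counts=counts,
        q=_ratio(counts.tp + counts.tn, counts.total),
        se=_ratio(counts.tp, counts.tp + counts.fn),
        sp=_ratio(counts.tn, counts.tn + counts.fp),
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
        endpoint=endpoint,
        n_alerts=n_alerts,
        stratum=stratum,
    )


def evaluate_alert_set(
    dataset: Dataset,
    alert_set: AlertSet,
    domain: DomainModel | None = None,
    ad_stratify: bool = False,
) -> MetricsReport | dict[str, MetricsReport | None]:
    """Screen a whole dataset with an alert set and summarize performance.

    Without stratification returns one :class:`MetricsReport`.  With
    ``ad_stratify`` (requires a domain model) returns a dict with keys
    ``all``, ``in_domain`` and ``out_of_domain``; an empty stratum maps
    to ``None``, and the stratum counts always sum to the ``all`` counts.
    """
    if len(dataset) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    if ad_stratify and domain is None:
        raise ValueError("ad_stratify requires a domain model")
    rows = []
    for compound in dataset:
        result = screen(compound, alert_set, domain)
        rows.append((1 if result.is_positive else 0, compound.label,
                     result.in_domain))
    all_counts = confusion([r[0] for r in rows], [r[1] for r in rows])
    report_all = metrics(all_counts, dataset.endpoint, len(alert_set), "all")
    if not ad_stratify:
        return report_all

    def _sub(flag: bool, name: str) -> MetricsReport | None:
        sub = [r for r in rows if r[2] is flag]
        if not sub:
            return None
        return metrics(
            confusion([r[0] for r in sub], [r[1] for r in sub]),
            dataset.endpoint, len(alert_set), name,
        )

    return {
        "all": report_all,
        "in_domain": _sub(True, "in_domain"),
        "out_of_domain": _sub(False, "out_of_domain"),
    }


def _pct(value: float | None) -> str:
    return "NA" if value is None else f"{100 * value:.2f}"


def report_frame(reports: Sequence[MetricsReport], n: int | None = None) -> pd.DataFrame:
    """Tabulate reports with percentages to two decimals (NA when undefined)."""
    rows = [
        {
            "endpoint": r.endpoint,
            "stratum": r.stratum,
            "n": r.counts.total,
            "n_alerts": r.n_alerts,
            "TP": r.counts.tp, "FP": r.counts.fp,
            "TN": r.counts.tn, "FN": r.counts.fn,
            "SE%": _pct(r.se), "SP%": _pct(r.sp),
            "Q%": _pct(r.q), "PPV%": _pct(r.ppv),
        }
        for r in reports
    ]
    return pd.DataFrame(rows)


def format_report(reports: Sequence[MetricsReport]) -> str:
    """Aligned-text rendering of :func:`report_frame`."""
    return report_frame(reports).to_string(index=False)
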