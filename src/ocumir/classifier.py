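"""Per-marker ROC analysis, fixed-sensitivity threshold selection, and the
conjunctive (AND-rule) two-marker classifier.

A single-marker rule calls the positive class when the marker's absolute
expression falls on the positive side of a threshold, boundary inclusive:
direction ``"low"`` calls positive iff value <= threshold, ``"high"`` iff
value >= threshold.  The published rules are

    miR-196b-5p <= 1172.258  ->  OSC   (marker higher in SCCC)
    miR-107     >= 365.4     ->  OSC   (marker higher in OSC)

and the combined classifier predicts OSC only when every rule does, trading
sensitivity for specificity.  Thresholds are trained on a discovery cohort by
choosing, among all candidate cut-offs reaching a required minimum sensitivity
(90% in the study), the one maximizing specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ROCCurve",
    "MarkerRule",
    "ClassificationReport",
    "INDETERMINATE",
    "roc_curve",
    "threshold_at_sensitivity",
    "apply_rule",
    "combined_and_classify",
    "classify_cohort",
    "evaluate",
]

#: Call emitted when a required marker value is missing.
INDETERMINATE = "indeterminate"

_DIRECTIONS = ("low", "high")  # positive-class-low / positive-class-high


@dataclass
class ROCCurve:
    marker: str
    direction: str  # "low": positives have low values; "high": high values
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    positive_class: str


@dataclass(frozen=True)
class MarkerRule:
    """One directional single-marker decision rule (boundary inclusive)."""

    marker: str
    threshold: float
    direction: str
    positive_class: str

    def __post_init__(self):
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}")
        if not np.isfinite(self.threshold) or self.threshold <= 0:
            raise ValueError(f"threshold must be finite and > 0, "
                             f"got {self.threshold}")


@dataclass
class ClassificationReport:
    """Confusion counts and operating point with the positive class fixed."""

    tp: int
    fn: int
    tn: int
    fp: int
    n_indeterminate: int
    positive_class: str
    calls: pd.DataFrame  # per-sample: sample_id, call, true_label

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else np.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else np.nan

    @property
    def sensitivity_pct(self) -> float:
        """Percentage sensitivity rounded to one decimal for reporting."""
        return round(100.0 * self.sensitivity, 1)

    @property
    def specificity_pct(self) -> float:
        return round(100.0 * self.specificity, 1)


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct sorted values plus sentinels.

    The sentinels (half the minimum, double the maximum) are finite and
    positive so they remain valid rule thresholds; they realise the two
    degenerate operating points (call none / call all on the positive side).
    """
    v = np.unique(values)
    mids = (v[:-1] + v[1:]) / 2.0
    return np.concatenate([[v[0] / 2.0], mids, [v[-1] * 2.0]])


def _calls_at(values: np.ndarray, threshold: float, direction: str) -> np.ndarray:
    return values <= threshold if direction == "low" else values >= threshold


def roc_curve(values, labels, positive_class: str, direction: str) -> ROCCurve:
    """ROC over all candidate thresholds for one marker.

    AUC is the Mann-Whitney probability that a random positive/negative pair
    is ordered correctly under ``direction``, ties counting 1/2.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")
    marker = getattr(values, "name", None) or "marker"
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must be aligned")
    if np.any(~np.isfinite(values)) or np.any(values <= 0):
        raise ValueError("marker values must be finite and > 0")
    pos = values[labels == positive_class]
    neg = values[labels != positive_class]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be represented")

    diff = pos[:, None] - neg[None, :]
    correct = (diff < 0) if direction == "low" else (diff > 0)
    auc = float((correct.sum() + 0.5 * (diff == 0).sum()) / diff.size)

    thr = _candidate_thresholds(values)
    sens = np.empty(thr.size)
    spec = np.empty(thr.size)
    for i, t in enumerate(thr):
        sens[i] = _calls_at(pos, t, direction).mean()
        spec[i] = 1.0 - _calls_at(neg, t, direction).mean()
    return ROCCurve(marker=marker, direction=direction, thresholds=thr,
                    sensitivity=sens, specificity=spec, auc=auc,
                    positive_class=positive_class)


def threshold_at_sensitivity(roc: ROCCurve, min_sensitivity: float,
                             marker: str | None = None) -> MarkerRule:
    """Pick the cut-off reaching ``min_sensitivity`` with maximal specificity.

    Among candidate thresholds whose sensitivity is at least the requested
    minimum, the one maximizing specificity wins; specificity ties go to the
    most stringent threshold (the one calling fewest samples positive).
    """
    if not 0 < min_sensitivity <= 1:
        raise ValueError("min_sensitivity must be in (0, 1]")
    ok = roc.sensitivity >= min_sensitivity
    if not ok.any():
        raise ValueError(
            f"no threshold reaches sensitivity {min_sensitivity:.2f}"
        )
    thr = roc.thresholds[ok]
    spec = roc.specificity[ok]
    best_spec = spec.max()
    tied = thr[spec == best_spec]
    # Fewest positives called: smallest threshold for "low", largest for "high".
    threshold = float(tied.min() if roc.direction == "low" else tied.max())
    return MarkerRule(marker=marker or roc.marker, threshold=threshold,
                      direction=roc.direction, positive_class=roc.positive_class)


def apply_rule(rule: MarkerRule, value, negative_class: str = "other") -> str:
    """Call one sample with one rule; a missing value is never classified."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return INDETERMINATE
    if rule.direction == "low":
        positive = value <= rule.threshold
    else:
        positive = value >= rule.threshold
    return rule.positive_class if positive else negative_class


def combined_and_classify(rules, sample_values,
                          negative_class: str = "other") -> str:
    """Conjunction of single-marker rules: positive only when every rule is.

    ``sample_values`` maps marker id -> value (a dict or Series).  A missing
    marker key is an error; a missing (NaN) value makes the combined call
    indeterminate.
    """
    rules = list(rules)
    if not rules:
        raise ValueError("need >= 1 rule")
    calls = []
    for rule in rules:
        if rule.marker not in sample_values:
            raise ValueError(f"no value for marker {rule.marker!r}")
        calls.append(apply_rule(rule, sample_values[rule.marker], negative_class))
    if INDETERMINATE in calls:
        return INDETERMINATE
    positive_class = rules[0].positive_class
    if all(c == positive_class for c in calls):
        return positive_class
    return negative_class


def classify_cohort(rules, table: pd.DataFrame,
                    negative_class: str = "other") -> pd.Series:
    """Apply the combined classifier to every row of a samples x markers table."""
    return pd.Series(
        {s: combined_and_classify(rules, table.loc[s], negative_class)
         for s in table.index},
        name="call",
    )


def evaluate(calls, true_labels, positive_class: str) -> ClassificationReport:
    """Confusion counts and operating point of per-sample calls vs truth.

    Indeterminate calls are counted and excluded from sensitivity and
    specificity, with the exclusion logged.  Percentages are rounded to one
    decimal for reporting; the raw fractions stay available on the report.
    """
    calls = pd.Series(calls)
    truth = pd.Series(true_labels)
    if len(calls) != len(truth):
        raise ValueError(f"calls ({len(calls)}) and labels ({len(truth)}) "
                         "must be aligned")
    truth.index = calls.index

    indet = calls == INDETERMINATE
    n_indet = int(indet.sum())
    if n_indet:
        logger.info("%d indeterminate call(s) excluded from the operating point",
                    n_indet)
    c, t = calls[~indet], truth[~indet]
    called_pos = c == positive_class
    is_pos = t == positive_class
    report = ClassificationReport(
        tp=int((called_pos & is_pos).sum()),
        fn=int((~called_pos & is_pos).sum()),
        tn=int((~called_pos & ~is_pos).sum()),
        fp=int((called_pos & ~is_pos).sum()),
        n_indeterminate=n_indet,
        positive_class=positive_class,
        calls=pd.DataFrame({"call": calls, "true_label": truth}),
    )
    return report
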