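"""Event-level validation: matching, confusion matrices, reliability metrics.

Predicted contact events are matched in time against ground-truth annotations
(greedy, by maximal temporal overlap, with a nearest-midpoint fallback within
a tolerance), and the matched labels fill a confusion matrix in which **rows
are the classifier's classes and columns the truth classes** — note this is
the transpose of the orientation many libraries use.

The seven-class layout is (mouth_nose, right_eye, left_eye, right_ear,
left_ear, low_risk, occlusion).  The classifier never emits an occlusion
label — a raised hand hiding the face without touching it produces plain
no-contact frames — so the occlusion *row* holds the events for which the
classifier emitted nothing (``no_detection``).  A truth occlusion event with
no matching prediction therefore lands on the (occlusion, occlusion) diagonal:
ignoring an occlusion is correct behavior.  Spurious predictions with no truth
counterpart are excluded from the matrix and reported separately, so the
matrix total equals the number of truth events.

Per class, with T the matrix total: TP is the diagonal cell, FP the rest of
the row, FN the rest of the column, TN the remainder, and

    accuracy    = (TP + TN) / T * 100
    precision   = TP / (TP + FP) * 100
    sensitivity = TP / (TP + FN) * 100

Overall accuracy is 100 * trace / T, and chance-corrected agreement is
Cohen's kappa = (p_o - p_e) / (1 - p_e) with p_e the product of the row and
column margins.  0/0 metrics are reported as NaN, never 0 or 100.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .skeleton_io import EVENT_LABELS, EventRecord, ValidationError

__all__ = [
    "CLASSES_7",
    "CLASSES_3",
    "ConfusionMatrix",
    "ClassMetrics",
    "MetricSet",
    "ClassClustering",
    "DEFAULT_CLUSTERING",
    "MatchResult",
    "match_events",
    "build_confusion",
    "per_class_metrics",
    "overall_accuracy",
    "cohens_kappa",
    "landis_koch_band",
    "cluster_matrix",
    "evaluate_events",
    "write_matrix_csv",
]

#: Fine (seven-class) layout: six contact classes + occlusion.
CLASSES_7: tuple[str, ...] = (
    "mouth_nose",
    "right_eye",
    "left_eye",
    "right_ear",
    "left_ear",
    "low_risk",
    "occlusion",
)

#: Coarse (three-class) layout after risk clustering.
CLASSES_3: tuple[str, ...] = ("risk_contacts", "no_risk_contacts", "occlusion")

#: Default matching tolerance for events without temporal overlap, seconds.
DEFAULT_TOLERANCE_S = 0.5


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer count matrix with rows = classifier classes, columns = truth."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        n = len(self.labels)
        if counts.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("confusion-matrix counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def cell(self, classifier_label: str, truth_label: str) -> int:
        return int(
            self.counts[self.labels.index(classifier_label), self.labels.index(truth_label)]
        )


@dataclass(frozen=True)
class ClassMetrics:
    """Base counts and advanced metrics for one class (percentages).

    Metrics with a zero denominator are NaN with ``undefined`` listing them.
    """

    label: str
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    sensitivity: float
    undefined: tuple[str, ...] = ()


@dataclass(frozen=True)
class MetricSet:
    """Per-class metrics plus overall accuracy and Cohen's kappa."""

    per_class: Mapping[str, ClassMetrics]
    overall_accuracy: float  # percent
    kappa: float
    kappa_band: str


@dataclass(frozen=True)
class ClassClustering:
    """Mapping from fine class labels to coarse ones, with coarse order."""

    mapping: Mapping[str, str]
    coarse_labels: tuple[str, ...]

    def coarse(self, fine_label: str) -> str:
        try:
            return self.mapping[fine_label]
        except KeyError:
            raise ValueError(f"clustering does not cover label {fine_label!r}") from None


#: Risk clustering: mucous-membrane contacts (mouth-nose, eyes) vs contacts
#: away from them (ears, low-risk area); occlusions stay their own class.
DEFAULT_CLUSTERING = ClassClustering(
    mapping={
        "mouth_nose": "risk_contacts",
        "right_eye": "risk_contacts",
        "left_eye": "risk_contacts",
        "right_ear": "no_risk_contacts",
        "left_ear": "no_risk_contacts",
        "low_risk": "no_risk_contacts",
        "occlusion": "occlusion",
    },
    coarse_labels=CLASSES_3,
)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of temporal event matching.

    ``pairs`` holds one (truth_label, classifier_label) pair per truth event,
    with ``no_detection`` for unmatched truth; ``spurious`` lists predictions
    with no truth counterpart.
    """

    pairs: list[tuple[str, str]]
    matched: list[tuple[EventRecord, Optional[EventRecord]]]
    spurious: list[EventRecord]


def _overlap(a: EventRecord, b: EventRecord) -> float:
    return min(a.end, b.end) - max(a.start, b.start)


def match_events(
    predicted: Sequence[EventRecord],
    truth: Sequence[EventRecord],
    tolerance_s: float = DEFAULT_TOLERANCE_S,
) -> MatchResult:
    """Greedily match predicted events to truth events by temporal overlap.

    Candidate pairs either overlap in time or have midpoints within
    *tolerance_s*.  Pairs are assigned greedily by descending overlap (ties:
    smaller midpoint distance, then earlier truth start), each event used at
    most once.  Truth events left unmatched are labeled ``no_detection``.
    """
    predicted = sorted(predicted, key=lambda e: (e.start, e.end, e.event_id))
    truth = sorted(truth, key=lambda e: (e.start, e.end, e.event_id))

    candidates: list[tuple[float, float, int, int]] = []
    for ti, t in enumerate(truth):
        for pi, p in enumerate(predicted):
            ov = _overlap(t, p)
            mid = abs(t.midpoint - p.midpoint)
            if ov > 0 or mid <= tolerance_s:
                candidates.append((-max(ov, 0.0), mid, ti, pi))
    candidates.sort()

    truth_match: dict[int, int] = {}
    used_pred: set[int] = set()
    for neg_ov, _mid, ti, pi in candidates:
        if ti in truth_match or pi in used_pred:
            continue
        truth_match[ti] = pi
        used_pred.add(pi)

    pairs: list[tuple[str, str]] = []
    matched: list[tuple[EventRecord, Optional[EventRecord]]] = []
    for ti, t in enumerate(truth):
        if ti in truth_match:
            p = predicted[truth_match[ti]]
            pairs.append((t.label, p.label))
            matched.append((t, p))
        else:
            pairs.append((t.label, "no_detection"))
            matched.append((t, None))
    spurious = [p for pi, p in enumerate(predicted) if pi not in used_pred]
    return MatchResult(pairs=pairs, matched=matched, spurious=spurious)


def build_confusion(
    pairs: Sequence[tuple[str, str]], labels: tuple[str, ...] = CLASSES_7
) -> ConfusionMatrix:
    """Tally (truth_label, classifier_label) pairs into a confusion matrix.

    The classifier's ``no_detection`` outcome occupies the occlusion row
    (the classifier has no occlusion output of its own), so missed truth
    events of any class are counted in that row.
    """
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for truth_label, pred_label in pairs:
        if truth_label not in index:
            raise ValidationError(f"truth label {truth_label!r} outside layout {labels}")
        row_label = pred_label
        if pred_label == "no_detection":
            if "occlusion" not in index:
                raise ValidationError("layout lacks an occlusion row for no_detection")
            row_label = "occlusion"
        if row_label not in index:
            raise ValidationError(f"classifier label {pred_label!r} outside layout {labels}")
        counts[index[row_label], index[truth_label]] += 1
    return ConfusionMatrix(labels=labels, counts=counts)


def per_class_metrics(cm: ConfusionMatrix) -> dict[str, ClassMetrics]:
    """TP/TN/FP/FN and accuracy/precision/sensitivity (Eqs. above) per class."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    rows, cols = cm.row_sums(), cm.col_sums()
    out: dict[str, ClassMetrics] = {}
    for i, label in enumerate(cm.labels):
        tp = int(cm.counts[i, i])
        fp = int(rows[i]) - tp
        fn = int(cols[i]) - tp
        tn = total - tp - fp - fn
        undefined: list[str] = []

        def ratio(num: int, den: int, name: str) -> float:
            if den == 0:
                undefined.append(name)
                return math.nan
            return 100.0 * num / den

        out[label] = ClassMetrics(
            label=label,
            tp=tp,
            tn=tn,
            fp=fp,
            fn=fn,
            accuracy=ratio(tp + tn, total, "accuracy"),
            precision=ratio(tp, tp + fp, "precision"),
            sensitivity=ratio(tp, tp + fn, "sensitivity"),
            undefined=tuple(undefined),
        )
    return out


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Percentage of truth events on the matrix diagonal."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * cm.trace / cm.total


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement between classifier and ground truth.

    kappa = (p_o - p_e) / (1 - p_e), p_e = sum_i row_i * col_i / total^2.
    Returns NaN when p_e = 1 (all mass in a single row and column), where
    chance correction is undefined.
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = cm.trace / total
    p_e = float(np.dot(cm.row_sums(), cm.col_sums())) / (total * total)
    if p_e >= 1.0:
        return math.nan
    return (p_o - p_e) / (1.0 - p_e)


def landis_koch_band(kappa: float) -> str:
    """Qualitative agreement band label for a kappa value."""
    if math.isnan(kappa):
        return "undefined"
    if kappa < 0.0:
        return "poor"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost_perfect"


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    """Full metric set: per-class, overall accuracy, kappa and its band."""
    kappa = cohens_kappa(cm)
    return MetricSet(
        per_class=per_class_metrics(cm),
        overall_accuracy=overall_accuracy(cm),
        kappa=kappa,
        kappa_band=landis_koch_band(kappa),
    )


def cluster_matrix(
    cm: ConfusionMatrix, clustering: ClassClustering = DEFAULT_CLUSTERING
) -> ConfusionMatrix:
    """Aggregate a fine confusion matrix into coarse classes.

    Each coarse cell is the sum of the fine cells mapping into it; the total
    is preserved.  Raises if the clustering does not cover every fine label.
    """
    coarse_index = {lab: i for i, lab in enumerate(clustering.coarse_labels)}
    n = len(clustering.coarse_labels)
    counts = np.zeros((n, n), dtype=int)
    for i, row_label in enumerate(cm.labels):
        ci = coarse_index[clustering.coarse(row_label)]
        for j, col_label in enumerate(cm.labels):
            cj = coarse_index[clustering.coarse(col_label)]
            counts[ci, cj] += cm.counts[i, j]
    return ConfusionMatrix(labels=clustering.coarse_labels, counts=counts)


def evaluate_events(
    predicted: Sequence[EventRecord],
    truth: Sequence[EventRecord],
    tolerance_s: float = DEFAULT_TOLERANCE_S,
    clustering: Optional[ClassClustering] = None,
) -> tuple[ConfusionMatrix, MetricSet, MatchResult]:
    """Match, tally and score predicted events against truth annotations.

    With *clustering* given, the seven-class matrix is built first and then
    collapsed, so the coarse matrix is exactly the clustered fine one.
    """
    result = match_events(predicted, truth, tolerance_s)
    cm = build_confusion(result.pairs, CLASSES_7)
    if clustering is not None:
        cm = cluster_matrix(cm, clustering)
    return cm, compute_metrics(cm), result


def write_matrix_csv(cm: ConfusionMatrix, path: Union[str, Path]) -> None:
    """Serialize with truth classes as columns, classifier classes as rows."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["classifier\\truth", *cm.labels])
        for i, label in enumerate(cm.labels):
            writer.writerow([label, *cm.counts[i].tolist()])
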