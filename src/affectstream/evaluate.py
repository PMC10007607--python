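"""Prequential evaluation: confusion accounting, metrics, and the
immediate and delayed validation protocols.

*Progressive (test-then-train) validation*: every labeled vector is first
classified by the current model, the prediction is scored, and only then
is the model updated with the true label — so each sample serves both as
test and training data without leaking its own label into its prediction.

*Delayed progressive validation*: in a live session the true label of a
stimulus only arrives after the stimulus ends.  Feature vectors are
classified on arrival and buffered; when a label tuple arrives, every
buffered prediction inside its time interval is scored (metric update),
and the model is then trained on those samples in window order.  Later
predictions use the updated model.  With zero delay this reduces exactly
to progressive validation.

Metrics are accuracy, ``(TP + TN) / (TP + TN + FP + FN)``, and the
F1-score in its equivalent single-fraction form
``TP / (TP + (FP + FN) / 2)``; the macro F1 averages the F1 computed
with *high* as the positive class and with *low* as the positive class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .devices import LabelTuple
from .featurize import FeatureVector
from .labels import binarize_rating
from .learners import HIGH, LOW, StreamClassifier

__all__ = [
    "ConfusionCounts",
    "TrajectoryPoint",
    "MetricTrajectory",
    "PredictionRecord",
    "accuracy",
    "f1",
    "macro_f1",
    "confusion_from_pairs",
    "metrics_from_pairs",
    "progressive_validate",
    "delayed_progressive_validate",
    "shuffled_repeats",
    "RepeatSummary",
]


@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN tallies relative to a declared positive class."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def add(self, predicted: int, true: int, positive: int = HIGH) -> None:
        if predicted == positive:
            if true == positive:
                self.tp += 1
            else:
                self.fp += 1
        else:
            if true == positive:
                self.fn += 1
            else:
                self.tn += 1

    def swapped(self) -> "ConfusionCounts":
        """The same predictions viewed with the other class as positive."""
        return ConfusionCounts(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp)


def accuracy(c: ConfusionCounts) -> float:
    """Fraction of correct predictions, (TP + TN) / total."""
    if c.total == 0:
        raise ValueError("accuracy undefined on empty confusion counts")
    return (c.tp + c.tn) / c.total


def f1(c: ConfusionCounts) -> float:
    """F1 = TP / (TP + (FP + FN)/2); 0 (with a warning) if no positives occur."""
    denom = c.tp + 0.5 * (c.fp + c.fn)
    if denom == 0:
        warnings.warn("F1 undefined (no positives predicted or present); returning 0.0")
        return 0.0
    return c.tp / denom


def macro_f1(counts_high: ConfusionCounts, counts_low: ConfusionCounts) -> float:
    """Mean of the F1 for the high-positive and low-positive views."""
    return 0.5 * (f1(counts_high) + f1(counts_low))


@dataclass(frozen=True)
class TrajectoryPoint:
    index: int
    accuracy: float
    f1_high: float
    f1_low: float
    macro_f1: float


@dataclass(frozen=True)
class PredictionRecord:
    """One scored prediction, as written to the predictions log."""

    t_start: float
    t_end: float
    predicted: int
    score: float
    true: int
    scored_at: float


@dataclass
class MetricTrajectory:
    """Cumulative prequential metric history plus the predictions log."""

    points: list[TrajectoryPoint] = field(default_factory=list)
    counts: ConfusionCounts = field(default_factory=ConfusionCounts)
    records: list[PredictionRecord] = field(default_factory=list)

    def score(self, record: PredictionRecord) -> None:
        self.records.append(record)
        self.counts.add(record.predicted, record.true)
        c = self.counts
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.points.append(
                TrajectoryPoint(
                    index=len(self.records),
                    accuracy=accuracy(c),
                    f1_high=f1(c),
                    f1_low=f1(c.swapped()),
                    macro_f1=macro_f1(c, c.swapped()),
                )
            )

    @property
    def final(self) -> TrajectoryPoint | None:
        return self.points[-1] if self.points else None


def confusion_from_pairs(
    pairs: Iterable[tuple[int, int]], positive: int = HIGH
) -> ConfusionCounts:
    """Confusion counts from (predicted, true) pairs — the offline
    recomputation oracle for any run's logged predictions."""
    c = ConfusionCounts()
    for pred, true in pairs:
        c.add(pred, true, positive)
    return c


def metrics_from_pairs(pairs: Sequence[tuple[int, int]]) -> dict[str, float]:
    """Accuracy / per-class F1 / macro F1 recomputed from logged pairs."""
    ch = confusion_from_pairs(pairs, positive=HIGH)
    cl = confusion_from_pairs(pairs, positive=LOW)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            "accuracy": accuracy(ch),
            "f1_high": f1(ch),
            "f1_low": f1(cl),
            "macro_f1": macro_f1(ch, cl),
        }


def progressive_validate(
    stream: Iterable[FeatureVector],
    clf: StreamClassifier,
    dimension: str,
) -> MetricTrajectory:
    """Test-then-train over a fully labeled stream.

    For each vector: predict with the current model, score the prediction
    against the vector's label for ``dimension``, then train on it.  Every
    sample is used for both validation and training; scoring strictly
    precedes learning.
    """
    traj = MetricTrajectory()
    for fv in stream:
        y = fv.label(dimension)
        if y is None:
            raise ValueError(
                f"progressive validation requires labeled vectors; window "
                f"[{fv.t_start}, {fv.t_end}] has no {dimension} label"
            )
        pred, score = clf.predict_one(fv.values)
        traj.score(
            PredictionRecord(fv.t_start, fv.t_end, pred, score, y, scored_at=fv.t_end)
        )
        clf.learn_one(fv.values, y)
    return traj


def delayed_progressive_validate(
    features: Iterable[FeatureVector],
    label_stream: Sequence[LabelTuple | tuple[float, LabelTuple]],
    clf: StreamClassifier,
    dimension: str,
    threshold: float = 0.5,
    on_unmatched: Callable[[LabelTuple], None] | None = None,
) -> MetricTrajectory:
    """Prequential evaluation when labels arrive after a delay.

    ``label_stream`` holds label tuples for ``dimension``, either bare
    (arrival time = ``t_end``) or as ``(arrival_time, tuple)`` pairs for
    induced-delay experiments.  Events are interleaved in event time:
    a feature vector arriving at its window's ``t_end`` is classified with
    the current model and buffered; a label tuple arriving at its arrival
    time first scores every buffered prediction whose window lies inside
    ``[t_start, t_end]`` (one metric update per prediction, in window
    order), then trains the model on those same samples in window order.
    Predictions left unmatched at stream end are reported via
    ``on_unmatched`` per orphaned label / kept in the returned trajectory's
    ``unmatched`` attribute.
    """
    labels: list[tuple[float, LabelTuple]] = []
    for item in label_stream:
        if isinstance(item, LabelTuple):
            labels.append((item.t_end, item))
        else:
            arrival, lt = item
            labels.append((float(arrival), lt))
    for _, lt in labels:
        if lt.dimension != dimension:
            raise ValueError(
                f"label stream contains {lt.dimension!r} tuple; expected {dimension!r}"
            )
    labels.sort(key=lambda p: p[0])

    traj = MetricTrajectory()
    pending: list[tuple[FeatureVector, int, float]] = []  # (fv, predicted, score)
    li = 0
    eps = 1e-9

    def _consume_labels(now: float | None) -> None:
        # a label arriving exactly when a window's feature vector does is
        # processed after that vector's prediction (test precedes train)
        nonlocal li, pending
        while li < len(labels) and (now is None or labels[li][0] < now - eps):
            arrival, lt = labels[li]
            li += 1
            matched = [
                p for p in pending
                if p[0].t_start >= lt.t_start - eps and p[0].t_end <= lt.t_end + eps
            ]
            if not matched:
                warnings.warn(
                    f"label tuple [{lt.t_start}, {lt.t_end}] matched no buffered "
                    f"predictions"
                )
                if on_unmatched is not None:
                    on_unmatched(lt)
                continue
            matched.sort(key=lambda p: p[0].t_start)
            y = binarize_rating(lt.rating, threshold)
            for fv, pred, score in matched:
                traj.score(
                    PredictionRecord(fv.t_start, fv.t_end, pred, score, y, scored_at=arrival)
                )
            for fv, _, _ in matched:
                clf.learn_one(fv.values, y)
            matched_ids = {id(p[0]) for p in matched}
            pending = [p for p in pending if id(p[0]) not in matched_ids]

    for fv in features:
        # label tuples that arrived strictly before this window's end are
        # processed first, so this prediction uses the freshest model
        _consume_labels(fv.t_end)
        pred, score = clf.predict_one(fv.values)
        pending.append((fv, pred, score))
    _consume_labels(None)
    traj.unmatched = [p[0] for p in pending]  # type: ignore[attr-defined]
    return traj


@dataclass(frozen=True)
class RepeatSummary:
    """Across-shuffle summary of a prequential run's final metrics."""

    per_repeat: tuple[TrajectoryPoint, ...]
    mean_macro_f1: float
    sd_macro_f1: float
    mean_accuracy: float
    sd_accuracy: float


def shuffled_repeats(
    labeled: Sequence[FeatureVector],
    clf_factory: Callable[[int], StreamClassifier],
    dimension: str,
    k: int = 10,
    base_seed: int = 0,
    holdout: bool = False,
) -> RepeatSummary:
    """k seeded shuffle-repeats of the full prequential run.

    Each repeat shuffles the labeled windows with a distinct derived seed
    and runs test-then-train on a fresh classifier, so every sample is
    still used for both testing and training in every repeat; the spread
    over repeats plays the role a fold spread plays offline.

    ``holdout=True`` switches to a classic 9/1 comparison mode: each
    repeat trains prequentially on the first 90% of its shuffle and
    scores predict-only on the held-out 10%, for comparing against the
    all-samples prequential reading.
    """
    from .featurize import shuffle_labeled_windows

    if k < 1:
        raise ValueError("k must be >= 1")
    finals: list[TrajectoryPoint] = []
    for rep in range(k):
        seed = int(np.random.default_rng((base_seed, rep)).integers(2**31 - 1))
        order = shuffle_labeled_windows(list(labeled), seed)
        clf = clf_factory(seed)
        if holdout:
            cut = max(1, int(round(0.9 * len(order))))
            if cut >= len(order):
                raise ValueError("too few windows for a 9/1 split")
            progressive_validate(order[:cut], clf, dimension)
            traj = MetricTrajectory()
            for fv in order[cut:]:
                pred, score = clf.predict_one(fv.values)
                traj.score(
                    PredictionRecord(
                        fv.t_start, fv.t_end, pred, score,
                        fv.label(dimension), scored_at=fv.t_end,
                    )
                )
        else:
            traj = progressive_validate(order, clf, dimension)
        if traj.final is None:
            raise ValueError("empty labeled stream")
        finals.append(traj.final)
    mf = np.array([p.macro_f1 for p in finals])
    ac = np.array([p.accuracy for p in finals])
    return RepeatSummary(
        per_repeat=tuple(finals),
        mean_macro_f1=float(mf.mean()),
        sd_macro_f1=float(mf.std(ddof=1)) if k > 1 else 0.0,
        mean_accuracy=float(ac.mean()),
        sd_accuracy=float(ac.std(ddof=1)) if k > 1 else 0.0,
    )
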