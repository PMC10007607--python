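import numpy as np
import pytest

from affectstream.devices import LabelTuple
from affectstream.evaluate import (
    ConfusionCounts,
    accuracy,
    confusion_from_pairs,
    delayed_progressive_validate,
    f1,
    macro_f1,
    metrics_from_pairs,
    progressive_validate,
    shuffled_repeats,
)
from affectstream.featurize import FeatureVector
from affectstream.learners import HIGH, LOW, LearnerConfig, OnlineLogisticRegression, make_classifier


class TestMetricFormulas:
    def test_accuracy_direct(self):
        assert accuracy(ConfusionCounts(tp=3, tn=4, fp=2, fn=1)) == pytest.approx(0.7)

    def test_accuracy_perfect_and_worst(self):
        assert accuracy(ConfusionCounts(tp=5, tn=5)) == 1.0
        assert accuracy(ConfusionCounts(fp=3, fn=2)) == 0.0

    def test_accuracy_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionCounts())

    def test_f1_single_fraction_form(self):
        assert f1(ConfusionCounts(tp=3, fp=1, fn=1)) == pytest.approx(0.75)
        assert f1(ConfusionCounts(tp=10)) == 1.0
        assert f1(ConfusionCounts(fp=2, fn=2)) == 0.0

    def test_f1_degenerate_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert f1(ConfusionCounts(tn=5)) == 0.0

    def test_macro_f1_mean(self):
        # f1_high = 0.8, f1_low = 0.6 -> macro 0.7 on hand-built counts
        high = ConfusionCounts(tp=4, fp=1, fn=1)  # 4 / 5 = 0.8
        low = ConfusionCounts(tp=3, fp=2, fn=2)  # 3 / 5 = 0.6
        assert macro_f1(high, low) == pytest.approx(0.7)

    def test_always_high_on_balanced_stream(self):
        # brute-force confusion enumeration: 100 samples, 50/50 classes,
        # classifier always says high -> macro F1 = (2/3 + 0)/2 = 1/3
        pairs = [(HIGH, HIGH)] * 50 + [(HIGH, LOW)] * 50
        m = metrics_from_pairs(pairs)
        assert m["f1_high"] == pytest.approx(2 / 3)
        assert m["f1_low"] == 0.0
        assert m["macro_f1"] == pytest.approx(1 / 3)


def _labeled_stream(n=300, seed=0, dimension="valence", separable=True, start=0.0):
    rng = np.random.default_rng(seed)
    xs = rng.normal(size=(n, 3))
    out = []
    for i, x in enumerate(xs):
        y = int(x[0] > 0) if separable else int(rng.integers(2))
        out.append(
            FeatureVector(x, start + float(i), start + float(i + 1), labels={dimension: y})
        )
    return out


class TestProgressive:
    def test_accuracy_rises_on_expressible_stream(self):
        stream = _labeled_stream(500)
        traj = progressive_validate(stream, OnlineLogisticRegression(3), "valence")
        assert len(traj.points) == 500
        early = traj.points[49].accuracy
        assert traj.final.accuracy > 0.8 > early + 0.1 or traj.final.accuracy > early

    def test_scoring_precedes_learning(self):
        # constant stream: the first trajectory entry must reflect the
        # untrained model's prediction (high at 0.5), even when y = low
        stream = [
            FeatureVector(np.array([1.0]), float(i), float(i + 1), labels={"valence": LOW})
            for i in range(5)
        ]
        traj = progressive_validate(stream, OnlineLogisticRegression(1), "valence")
        assert traj.records[0].predicted == HIGH
        assert traj.records[0].score == 0.5
        assert traj.points[0].accuracy == 0.0

    def test_empty_stream_empty_trajectory(self):
        traj = progressive_validate([], OnlineLogisticRegression(2), "valence")
        assert traj.points == [] and traj.final is None

    def test_unlabeled_vector_rejected(self):
        stream = [FeatureVector(np.zeros(2), 0.0, 1.0)]
        with pytest.raises(ValueError, match="no valence label"):
            progressive_validate(stream, OnlineLogisticRegression(2), "valence")

    def test_confusion_totals_conservation(self):
        stream = _labeled_stream(123)
        traj = progressive_validate(stream, OnlineLogisticRegression(3), "valence")
        assert traj.counts.total == len(traj.records) == 123


class TestDelayed:
    def test_zero_delay_equals_progressive(self):
        """With each window's label arriving immediately after it, the
        delayed protocol reproduces test-then-train exactly."""
        stream = _labeled_stream(200, seed=4)
        labels = [
            LabelTuple("valence", 1.0 if fv.label("valence") == HIGH else 0.0,
                       fv.t_start, fv.t_end)
            for fv in stream
        ]
        t1 = progressive_validate(stream, OnlineLogisticRegression(3), "valence")
        t2 = delayed_progressive_validate(stream, labels, OnlineLogisticRegression(3), "valence")
        assert [(r.predicted, r.true) for r in t1.records] == [
            (r.predicted, r.true) for r in t2.records
        ]
        assert t1.points == t2.points

    def test_single_video_buffering(self):
        """One 86-window video labeled at its end: all 86 predictions are
        made by the pre-label model, then scored and learned at arrival."""
        stream = _labeled_stream(86, seed=2)
        label = LabelTuple("valence", 0.9, 0.0, 86.0)
        clf = OnlineLogisticRegression(3)
        traj = delayed_progressive_validate(stream, [label], clf, "valence")
        assert len(traj.records) == 86
        # every prediction was made before any learning: the untrained LR
        # always answers (high, 0.5)
        assert all(r.score == 0.5 and r.predicted == HIGH for r in traj.records)
        assert clf.n_seen == 86
        assert all(r.scored_at == 86.0 for r in traj.records)

    def test_causality_label_after_next_video_started(self):
        """Video-2 predictions are made by the model not yet updated with
        video-1 labels when those labels arrive late."""
        v1 = _labeled_stream(10, seed=1, start=0.0)
        v2 = _labeled_stream(10, seed=2, start=10.0)
        late = 25.0
        labels = [(late, LabelTuple("valence", 1.0, 0.0, 10.0))]
        clf = OnlineLogisticRegression(3)
        traj = delayed_progressive_validate(v1 + v2, labels, clf, "valence")
        # only video-1 windows were ever scored; all with the untrained model
        assert len(traj.records) == 10
        assert all(r.score == 0.5 for r in traj.records)
        assert len(traj.unmatched) == 10

    def test_unmatched_label_warns(self):
        stream = _labeled_stream(5, start=100.0)
        labels = [LabelTuple("valence", 0.8, 0.0, 10.0)]
        with pytest.warns(UserWarning, match="matched no buffered"):
            delayed_progressive_validate(stream, labels, OnlineLogisticRegression(3), "valence")

    def test_wrong_dimension_rejected(self):
        with pytest.raises(ValueError, match="expected 'valence'"):
            delayed_progressive_validate(
                [], [LabelTuple("arousal", 0.5, 0.0, 1.0)],
                OnlineLogisticRegression(3), "valence",
            )


class TestRecomputationOracle:
    def test_final_metrics_match_offline_recomputation(self):
        stream = _labeled_stream(250, seed=6)
        traj = progressive_validate(stream, OnlineLogisticRegression(3), "valence")
        pairs = [(r.predicted, r.true) for r in traj.records]
        m = metrics_from_pairs(pairs)
        assert m["accuracy"] == traj.final.accuracy
        assert m["f1_high"] == traj.final.f1_high
        assert m["f1_low"] == traj.final.f1_low
        assert m["macro_f1"] == traj.final.macro_f1
        c = confusion_from_pairs(pairs)
        assert (c.tp, c.tn, c.fp, c.fn) == (
            traj.counts.tp, traj.counts.tn, traj.counts.fp, traj.counts.fn,
        )


class TestShuffledRepeats:
    @staticmethod
    def _factory(seed):
        return OnlineLogisticRegression(3)

    def test_reproducible_and_distinct_permutations(self):
        labeled = _labeled_stream(120, seed=8)
        a = shuffled_repeats(labeled, self._factory, "valence", k=4, base_seed=5)
        b = shuffled_repeats(labeled, self._factory, "valence", k=4, base_seed=5)
        assert a == b
        assert len(a.per_repeat) == 4

    def test_label_permuted_data_near_chance(self):
        labeled = _labeled_stream(400, seed=9, separable=False)
        s = shuffled_repeats(labeled, self._factory, "valence", k=10, base_seed=1)
        assert abs(s.mean_macro_f1 - 0.5) < 3 * max(s.sd_macro_f1, 0.02)

    def test_holdout_mode_scores_only_final_tenth(self):
        labeled = _labeled_stream(200, seed=2)
        s = shuffled_repeats(labeled, self._factory, "valence", k=2, base_seed=3,
                             holdout=True)
        # 10% of 200 windows are scored per repeat
        assert all(p.index == 20 for p in s.per_repeat)

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError, match="k"):
            shuffled_repeats(_labeled_stream(10), self._factory, "valence", k=0)
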