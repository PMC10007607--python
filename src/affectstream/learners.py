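"""Incremental classifiers with a learn-one / predict-one contract.

Every learner here consumes one feature vector at a time and can emit a
prediction before seeing that vector's label, which is what prequential
(test-then-train) evaluation requires.  Three kinds are provided:

``lr``
    Online logistic regression trained by plain stochastic gradient
    descent on the log-loss, one sample per step, learning rate 0.1, no
    regularization — the naive baseline.
``arf``
    An adaptive-random-forest-style ensemble: incremental Hoeffding trees
    grown under online bagging (Poisson(6) example weighting), each tree
    restricted to a random sqrt-size feature subset at every leaf, with a
    per-tree error-rate drift monitor that resets a degrading tree.
``srp``
    A streaming-random-patches-style ensemble: the same base trees, but
    each ensemble member sees a fixed random patch (subset) of the feature
    space for its whole lifetime, plus the same bagging and drift reset.

The Hoeffding tree is a compact implementation of the classic VFDT idea:
leaves accumulate per-class Gaussian sufficient statistics per feature,
and a leaf splits on the best binary threshold once the Hoeffding bound
guarantees (with confidence 1 - delta) that the observed information-gain
advantage over the runner-up is real.  The drift monitor follows the DDM
rule: a tree whose running error rate rises three standard deviations
above its historical minimum is replaced by a fresh tree.

Classes are encoded 0 = low, 1 = high everywhere; scores are P(high).
An untrained classifier predicts high with score 0.5 (consistent with the
"ties go to high" labeling rule).
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

__all__ = [
    "StreamClassifier",
    "LearnerConfig",
    "OnlineLogisticRegression",
    "HoeffdingTree",
    "AdaptiveForest",
    "RandomPatchesEnsemble",
    "make_classifier",
    "classifier_to_blob",
    "classifier_from_blob",
]

LOW, HIGH = 0, 1


@runtime_checkable
class StreamClassifier(Protocol):
    """The learn-one / predict-one contract shared by all learners."""

    n_seen: int

    def predict_one(self, x: np.ndarray) -> tuple[int, float]:
        """Classify one vector; returns (class, P(high)). Never mutates state."""
        ...

    def learn_one(self, x: np.ndarray, y: int) -> "StreamClassifier":
        """Update on one labeled vector; increments ``n_seen``."""
        ...


@dataclass(frozen=True)
class LearnerConfig:
    """Which classifier to build and with what knobs."""

    kind: str = "arf"  # "lr" | "arf" | "srp"
    n_trees: int = 5
    learning_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("lr", "arf", "srp"):
            raise ValueError(f"unknown learner kind {self.kind!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def _check_dim(x: np.ndarray, n_features: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (n_features,):
        raise ValueError(f"expected feature vector of length {n_features}, got shape {x.shape}")
    return x


def _sigmoid(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


class OnlineLogisticRegression:
    """Logistic regression trained one sample at a time by SGD on log-loss.

    The update for a sample ``(x, y)`` with current probability
    ``p = sigmoid(w.x + b)`` is ``w += lr (y - p) x`` and
    ``b += lr (y - p)`` — a single unregularized gradient step.
    """

    def __init__(self, n_features: int, learning_rate: float = 0.1) -> None:
        if n_features < 1:
            raise ValueError("n_features must be >= 1")
        if learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        self.n_features = n_features
        self.learning_rate = learning_rate
        self.weights = np.zeros(n_features)
        self.bias = 0.0
        self.n_seen = 0

    def predict_one(self, x: np.ndarray) -> tuple[int, float]:
        x = _check_dim(x, self.n_features)
        p = _sigmoid(float(self.weights @ x) + self.bias)
        return (HIGH if p >= 0.5 else LOW), p

    def learn_one(self, x: np.ndarray, y: int) -> "OnlineLogisticRegression":
        x = _check_dim(x, self.n_features)
        if y not in (LOW, HIGH):
            raise ValueError(f"class must be 0 (low) or 1 (high), got {y}")
        p = _sigmoid(float(self.weights @ x) + self.bias)
        residual = self.learning_rate * (y - p)
        self.weights += residual * x
        self.bias += residual
        self.n_seen += 1
        return self


# --------------------------------------------------------------------------
# Hoeffding tree
# --------------------------------------------------------------------------


class _GaussianStat:
    """Welford-updated running Gaussian (n, mean, variance) for one
    feature under one class."""

    __slots__ = ("n", "mean", "_m2")

    def __init__(self) -> None:
        self.n = 0
        self.mean = 0.0
        self._m2 = 0.0

    def update(self, v: float, w: int = 1) -> None:
        for _ in range(w):
            self.n += 1
            d = v - self.mean
            self.mean += d / self.n
            self._m2 += d * (v - self.mean)

    @property
    def std(self) -> float:
        if self.n < 2:
            return 0.0
        return math.sqrt(self._m2 / (self.n - 1))

    def cdf(self, t: float) -> float:
        """P(value <= t) under the fitted Gaussian."""
        if self.n == 0:
            return 0.0
        s = self.std
        if s <= 1e-300:
            return 1.0 if t >= self.mean else 0.0
        return 0.5 * (1.0 + math.erf((t - self.mean) / (s * math.sqrt(2.0))))


def _entropy(counts: Sequence[float]) -> float:
    tot = sum(counts)
    if tot <= 0:
        return 0.0
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / tot
            h -= p * math.log2(p)
    return h


class _Leaf:
    __slots__ = ("class_counts", "stats", "fmin", "fmax", "features", "n_since_split")

    def __init__(self, features: np.ndarray) -> None:
        self.class_counts = [0.0, 0.0]
        # stats[f] = (low-class Gaussian, high-class Gaussian), lazily built
        self.stats: dict[int, tuple[_GaussianStat, _GaussianStat]] = {}
        self.fmin: dict[int, float] = {}
        self.fmax: dict[int, float] = {}
        self.features = features  # candidate split features at this leaf
        self.n_since_split = 0

    def update(self, x: np.ndarray, y: int, w: int) -> None:
        self.class_counts[y] += w
        self.n_since_split += w
        for f in self.features:
            v = float(x[f])
            if f not in self.stats:
                self.stats[f] = (_GaussianStat(), _GaussianStat())
                self.fmin[f] = v
                self.fmax[f] = v
            self.stats[f][y].update(v, w)
            self.fmin[f] = min(self.fmin[f], v)
            self.fmax[f] = max(self.fmax[f], v)


class _Split:
    __slots__ = ("feature", "threshold", "left", "right")

    def __init__(self, feature: int, threshold: float, left, right) -> None:
        self.feature = feature
        self.threshold = threshold
        self.left = left
        self.right = right


class HoeffdingTree:
    """Incremental decision tree with Hoeffding-bound split decisions.

    ``subspace_size``: number of candidate split features drawn fresh per
    leaf (``None`` = all features); this is the per-node randomization the
    forest relies on.
    """

    N_SPLIT_POINTS = 10

    def __init__(
        self,
        n_features: int,
        grace_period: int = 200,
        delta: float = 1e-7,
        tau: float = 0.05,
        max_depth: int = 20,
        subspace_size: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.n_features = n_features
        self.grace_period = grace_period
        self.delta = delta
        self.tau = tau
        self.max_depth = max_depth
        self.subspace_size = subspace_size
        self._rng = rng or np.random.default_rng(0)
        self.n_seen = 0
        self._root = self._new_leaf()

    def _new_leaf(self) -> _Leaf:
        if self.subspace_size is None or self.subspace_size >= self.n_features:
            feats = np.arange(self.n_features)
        else:
            feats = self._rng.choice(self.n_features, self.subspace_size, replace=False)
        return _Leaf(feats)

    def _route(self, x: np.ndarray) -> _Leaf:
        node = self._root
        while isinstance(node, _Split):
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node

    def predict_one(self, x: np.ndarray) -> tuple[int, float]:
        x = _check_dim(x, self.n_features)
        leaf = self._route(x)
        n0, n1 = leaf.class_counts
        p = (n1 + 1.0) / (n0 + n1 + 2.0)  # Laplace-smoothed P(high)
        return (HIGH if p >= 0.5 else LOW), p

    def learn_one(self, x: np.ndarray, y: int, weight: int = 1) -> "HoeffdingTree":
        x = _check_dim(x, self.n_features)
        if y not in (LOW, HIGH):
            raise ValueError(f"class must be 0 or 1, got {y}")
        leaf, depth, parent, side = self._root, 0, None, None
        while isinstance(leaf, _Split):
            parent, side = leaf, ("left" if x[leaf.feature] <= leaf.threshold else "right")
            leaf = getattr(leaf, side)
            depth += 1
        leaf.update(x, y, weight)
        self.n_seen += weight
        if leaf.n_since_split >= self.grace_period and depth < self.max_depth:
            leaf.n_since_split = 0
            split = self._attempt_split(leaf)
            if split is not None:
                if parent is None:
                    self._root = split
                else:
                    setattr(parent, side, split)
        return self

    # -- split machinery ---------------------------------------------------

    def _hoeffding_bound(self, n: float) -> float:
        # R = log2(2) = 1 for binary-class information gain
        return math.sqrt(math.log(1.0 / self.delta) / (2.0 * n))

    def _gain(self, leaf: _Leaf, f: int, t: float) -> float:
        lo_stat, hi_stat = leaf.stats[f]
        n0, n1 = leaf.class_counts
        l0 = n0 * lo_stat.cdf(t) if lo_stat.n else 0.0
        l1 = n1 * hi_stat.cdf(t) if hi_stat.n else 0.0
        r0, r1 = n0 - l0, n1 - l1
        tot = n0 + n1
        nl, nr = l0 + l1, r0 + r1
        if tot <= 0:
            return 0.0
        h_parent = _entropy((n0, n1))
        h_split = (nl / tot) * _entropy((l0, l1)) + (nr / tot) * _entropy((r0, r1))
        return h_parent - h_split

    def _attempt_split(self, leaf: _Leaf) -> _Split | None:
        n = sum(leaf.class_counts)
        if n < 2 or min(leaf.class_counts) == 0:
            return None
        best: tuple[float, int, float] | None = None
        second_gain = 0.0
        for f in leaf.features:
            if f not in leaf.stats:
                continue
            lo, hi = leaf.fmin[f], leaf.fmax[f]
            if hi <= lo:
                continue
            step = (hi - lo) / (self.N_SPLIT_POINTS + 1)
            for k in range(1, self.N_SPLIT_POINTS + 1):
                t = lo + k * step
                g = self._gain(leaf, f, t)
                if best is None or g > best[0]:
                    if best is not None:
                        second_gain = best[0]
                    best = (g, f, t)
                elif g > second_gain:
                    second_gain = g
        if best is None:
            return None
        bound = self._hoeffding_bound(n)
        if best[0] - second_gain > bound or bound < self.tau:
            if best[0] <= 0.0:
                return None
            return _Split(best[1], best[2], self._new_leaf(), self._new_leaf())
        return None


# --------------------------------------------------------------------------
# Drift-monitored bagging ensembles
# --------------------------------------------------------------------------


class _DDM:
    """Drift detection on a Bernoulli error stream (the DDM rule).

    Tracks the running error rate p and its binomial standard deviation s;
    once p + s exceeds the historical minimum of p + s by three of its
    standard deviations, drift is signaled.
    """

    __slots__ = ("n", "errors", "p_min", "s_min")
    MIN_SAMPLES = 30

    def __init__(self) -> None:
        self.n = 0
        self.errors = 0
        self.p_min = math.inf
        self.s_min = math.inf

    def update(self, error: bool) -> bool:
        self.n += 1
        self.errors += int(error)
        if self.n < self.MIN_SAMPLES:
            return False
        p = self.errors / self.n
        s = math.sqrt(p * (1.0 - p) / self.n)
        if p + s < self.p_min + self.s_min:
            self.p_min, self.s_min = p, s
        return p + s > self.p_min + 3.0 * self.s_min


class _BaggedTreeEnsemble:
    """Online bagging of Hoeffding trees with per-tree drift resets.

    Each ``learn_one`` draws a Poisson(6) weight per tree (online
    bootstrap), updates the tree's drift monitor with its own prequential
    error on the incoming sample, and resets any tree whose monitor fires.
    Prediction averages the member trees' class probabilities.
    """

    _POISSON_LAMBDA = 6.0

    def __init__(self, n_features: int, n_trees: int, seed: int) -> None:
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.n_features = n_features
        self.n_trees = n_trees
        self.seed = seed
        self._rng = np.random.default_rng(seed)
        self._trees = [self._make_tree(i) for i in range(n_trees)]
        self._detectors = [_DDM() for _ in range(n_trees)]
        self.n_seen = 0

    def _make_tree(self, index: int) -> HoeffdingTree:  # pragma: no cover - abstract
        raise NotImplementedError

    def _member_x(self, index: int, x: np.ndarray) -> np.ndarray:
        return x

    def predict_one(self, x: np.ndarray) -> tuple[int, float]:
        x = _check_dim(x, self.n_features)
        p = float(
            np.mean([t.predict_one(self._member_x(i, x))[1] for i, t in enumerate(self._trees)])
        )
        return (HIGH if p >= 0.5 else LOW), p

    def learn_one(self, x: np.ndarray, y: int) -> "_BaggedTreeEnsemble":
        x = _check_dim(x, self.n_features)
        if y not in (LOW, HIGH):
            raise ValueError(f"class must be 0 or 1, got {y}")
        for i, tree in enumerate(self._trees):
            xi = self._member_x(i, x)
            pred, _ = tree.predict_one(xi)
            if self._detectors[i].update(pred != y):
                self._trees[i] = self._make_tree(i)
                self._detectors[i] = _DDM()
                tree = self._trees[i]
            k = int(self._rng.poisson(self._POISSON_LAMBDA))
            if k > 0:
                tree.learn_one(xi, y, weight=k)
        self.n_seen += 1
        return self


class AdaptiveForest(_BaggedTreeEnsemble):
    """ARF-style forest: per-leaf random feature subsets of size sqrt(F)."""

    def _make_tree(self, index: int) -> HoeffdingTree:
        m = max(1, int(round(math.sqrt(self.n_features))))
        return HoeffdingTree(
            self.n_features,
            subspace_size=m,
            rng=np.random.default_rng((self.seed, 1, index, 0x5F)),
        )


class RandomPatchesEnsemble(_BaggedTreeEnsemble):
    """SRP-style ensemble: each member sees a fixed random feature patch."""

    PATCH_FRACTION = 0.6

    def __init__(self, n_features: int, n_trees: int, seed: int) -> None:
        self._patches: list[np.ndarray] = []
        rng = np.random.default_rng((seed, 2, 0xA7))
        size = max(1, int(round(self.PATCH_FRACTION * n_features)))
        for _ in range(n_trees):
            self._patches.append(np.sort(rng.choice(n_features, size, replace=False)))
        super().__init__(n_features, n_trees, seed)

    def _make_tree(self, index: int) -> HoeffdingTree:
        return HoeffdingTree(
            len(self._patches[index]),
            rng=np.random.default_rng((self.seed, 3, index, 0xB3)),
        )

    def _member_x(self, index: int, x: np.ndarray) -> np.ndarray:
        return x[self._patches[index]]


def make_classifier(cfg: LearnerConfig, n_features: int) -> StreamClassifier:
    """Build the configured classifier for a given feature dimensionality."""
    if cfg.kind == "lr":
        return OnlineLogisticRegression(n_features, cfg.learning_rate)
    if cfg.kind == "arf":
        return AdaptiveForest(n_features, cfg.n_trees, cfg.seed)
    if cfg.kind == "srp":
        return RandomPatchesEnsemble(n_features, cfg.n_trees, cfg.seed)
    raise ValueError(f"unknown learner kind {cfg.kind!r}")


_BLOB_VERSION = 1


def classifier_to_blob(clf: StreamClassifier) -> bytes:
    """Serialize a classifier to a versioned blob (for the live two-part
    protocol, where the model trained on part 1 resumes in part 2)."""
    return pickle.dumps({"version": _BLOB_VERSION, "classifier": clf})


def classifier_from_blob(blob: bytes) -> StreamClassifier:
    payload = pickle.loads(blob)
    if payload.get("version") != _BLOB_VERSION:
        raise ValueError(f"unsupported classifier blob version {payload.get('version')}")
    return payload["classifier"]
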