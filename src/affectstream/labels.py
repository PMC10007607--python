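"""Rating normalization, binary thresholding, and interval label matching.

Self-reported affect ratings arrive on one of two scales: the Affective
Slider's continuous unit scale [0, 1], or the 1-9 Self-Assessment Manikin
used by older datasets.  Both are normalized to [0, 1]; a single threshold
at 0.5 then splits each dimension into *low* and *high* classes (ties go
to high, so the SAM midpoint 5 maps to the class boundary).

Labels reach windows through their timestamps: a rating tuple covering
``[t_start, t_end]`` labels exactly the feature windows lying wholly
inside that interval, independently per dimension.
"""

from __future__ import annotations

from typing import Sequence

from .devices import LabelTuple
from .featurize import FeatureVector

__all__ = ["normalize_rating", "binarize_rating", "assign_labels", "LOW", "HIGH"]

LOW, HIGH = 0, 1


def normalize_rating(raw: float, scale: str = "unit") -> float:
    """Map a raw rating onto the unit scale.

    ``unit`` is the identity on [0, 1]; ``sam9`` maps the 1-9 SAM scale
    affinely, ``(raw - 1) / 8``, so the scale midpoint 5 lands on 0.5.
    """
    if scale == "unit":
        if not 0.0 <= raw <= 1.0:
            raise ValueError(f"unit-scale rating must be in [0, 1], got {raw}")
        return float(raw)
    if scale == "sam9":
        if not 1.0 <= raw <= 9.0:
            raise ValueError(f"SAM rating must be in [1, 9], got {raw}")
        return (float(raw) - 1.0) / 8.0
    raise ValueError(f"unknown rating scale {scale!r}")


def binarize_rating(rating: float, threshold: float = 0.5) -> int:
    """Threshold a unit-scale rating into a binary class (1=high, 0=low)."""
    if not 0.0 <= rating <= 1.0:
        raise ValueError(f"rating must be in [0, 1], got {rating}")
    return HIGH if rating >= threshold else LOW


def assign_labels(
    features: Sequence[FeatureVector],
    tuples: Sequence[LabelTuple],
    threshold: float = 0.5,
) -> list[FeatureVector]:
    """Attach binarized labels to the feature vectors each tuple covers.

    A feature vector receives tuple *j*'s class for a dimension iff its
    window lies within ``[t_start_j, t_end_j]``.  Windows matching no
    tuple stay unlabeled for that dimension.  Overlapping tuples within
    one dimension are ambiguous ground truth and raise.  Mutates and
    returns ``features``.
    """
    by_dim: dict[str, list[LabelTuple]] = {}
    for t in tuples:
        by_dim.setdefault(t.dimension, []).append(t)
    for dim, ts in by_dim.items():
        ts.sort(key=lambda t: t.t_start)
        for a, b in zip(ts, ts[1:]):
            if b.t_start < a.t_end:
                raise ValueError(
                    f"overlapping {dim} label tuples: "
                    f"[{a.t_start}, {a.t_end}] and [{b.t_start}, {b.t_end}]"
                )
    eps = 1e-9
    for f in features:
        for dim, ts in by_dim.items():
            for t in ts:
                if f.t_start >= t.t_start - eps and f.t_end <= t.t_end + eps:
                    if f.labels is None:
                        f.labels = {}
                    f.labels[dim] = binarize_rating(t.rating, threshold)
                    break
    return list(features)
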