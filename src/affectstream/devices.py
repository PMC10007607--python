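"""Device profiles, recording and label-stream I/O, and stream replay.

Consumer EEG headsets are described by a :class:`DeviceProfile` (channel
montage in 10-20 labels plus sampling rate).  Recordings are plain CSV
tables — one row per sample, a ``timestamp`` column in float seconds from
stream start and one column per channel in microvolts — so that a recorded
session can be replayed through the streaming pipeline exactly as it
arrived.  Affect self-reports travel as delayed label tuples
``(dimension, rating, t_start, t_end)``: one rating per stimulus and
dimension, covering the stimulus interval, delivered after the stimulus
ends.
"""

from __future__ import annotations

import csv
import time
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DeviceProfile",
    "Sample",
    "Recording",
    "LabelTuple",
    "UnknownProfileError",
    "builtin_profile",
    "BUILTIN_PROFILES",
    "read_recording",
    "write_recording",
    "replay_stream",
    "attach_arrival_timestamps",
    "read_label_stream",
    "write_label_stream",
]

DIMENSIONS = ("arousal", "valence")


class UnknownProfileError(KeyError):
    """Raised when a device-profile name has no built-in definition."""


@dataclass(frozen=True)
class DeviceProfile:
    """Channel layout and sampling rate of a named EEG headset."""

    name: str
    sampling_rate: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not self.channel_names:
            raise ValueError("profile needs at least one channel")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


@dataclass(frozen=True)
class Sample:
    """One timestamped multichannel EEG reading (stream element)."""

    timestamp: float
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.timestamp):
            raise ValueError("sample timestamp must be finite")


@dataclass
class Recording:
    """An ordered sequence of samples from one device session."""

    profile: DeviceProfile
    samples: list[Sample]

    def __post_init__(self) -> None:
        for i, s in enumerate(self.samples):
            if len(s.values) != self.profile.n_channels:
                raise ValueError(
                    f"sample {i} has {len(s.values)} values, profile has "
                    f"{self.profile.n_channels} channels"
                )
        ts = [s.timestamp for s in self.samples]
        for i in range(1, len(ts)):
            if ts[i] < ts[i - 1]:
                raise ValueError(f"timestamps not sorted at row {i}")
            if ts[i] == ts[i - 1]:
                raise ValueError(f"duplicate timestamp at row {i}")

    def __len__(self) -> int:
        return len(self.samples)

    def to_array(self) -> np.ndarray:
        """Samples as a (n_samples, n_channels) float array."""
        return np.array([s.values for s in self.samples], dtype=float)

    def timestamps(self) -> np.ndarray:
        return np.array([s.timestamp for s in self.samples], dtype=float)


@dataclass(frozen=True)
class LabelTuple:
    """A delayed affect rating covering one stimulus interval.

    ``rating`` is on the normalized unit scale; ``t_start``/``t_end`` bound
    the stimulus the rating refers to.  The tuple becomes available only at
    (or after) ``t_end`` — that lag is the delayed-label problem.
    """

    dimension: str
    rating: float
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"dimension must be one of {DIMENSIONS}, got {self.dimension!r}")
        if not 0.0 <= self.rating <= 1.0:
            raise ValueError(f"rating must be in [0, 1], got {self.rating}")
        if not self.t_start < self.t_end:
            raise ValueError(f"t_start must precede t_end ({self.t_start} >= {self.t_end})")


_BUILTINS = {
    "muse_s": DeviceProfile("muse_s", 256.0, ("AF7", "AF8", "TP9", "TP10")),
    "crown": DeviceProfile(
        "crown", 256.0, ("C3", "C4", "CP3", "CP4", "F5", "F6", "PO3", "PO4")
    ),
    "epoc": DeviceProfile(
        "epoc",
        128.0,
        (
            "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
            "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
        ),
    ),
}

BUILTIN_PROFILES = tuple(_BUILTINS)


def builtin_profile(name: str) -> DeviceProfile:
    """Return the built-in profile for ``muse_s``, ``crown`` or ``epoc``."""
    try:
        return _BUILTINS[name]
    except KeyError:
        raise UnknownProfileError(
            f"unknown device profile {name!r}; known: {sorted(_BUILTINS)}"
        ) from None


def read_recording(path, profile: DeviceProfile) -> Recording:
    """Read a recording CSV, matching channel columns to the profile by name.

    The file must have a ``timestamp`` column plus exactly the profile's
    channels (any column order).  Rows must be numeric and sorted by
    timestamp.
    """
    df = pd.read_csv(path)
    if "timestamp" not in df.columns:
        raise ValueError(f"{path}: missing 'timestamp' column")
    have = set(df.columns) - {"timestamp"}
    want = set(profile.channel_names)
    if have != want:
        missing, extra = sorted(want - have), sorted(have - want)
        raise ValueError(
            f"{path}: channel columns do not match profile {profile.name!r} "
            f"(missing {missing}, unexpected {extra})"
        )
    ordered = df[["timestamp", *profile.channel_names]]
    arr = ordered.to_numpy(dtype=float)  # raises on non-numeric cells
    if not np.all(np.isfinite(arr)):
        bad = int(np.argwhere(~np.isfinite(arr))[0][0])
        raise ValueError(f"{path}: non-finite value at data row {bad}")
    ts = arr[:, 0]
    if np.any(np.diff(ts) < 0):
        bad = int(np.argmin(np.diff(ts) >= 0)) + 1
        raise ValueError(f"{path}: timestamps not sorted at data row {bad}")
    samples = [Sample(float(r[0]), tuple(r[1:])) for r in arr]
    return Recording(profile, samples)


def write_recording(recording: Recording, path, decimals: int = 6) -> None:
    """Write a recording CSV (round-trips with :func:`read_recording`)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["timestamp", *recording.profile.channel_names])
        for s in recording.samples:
            w.writerow(
                [format(s.timestamp, f".{decimals}f")]
                + [format(v, f".{decimals}f") for v in s.values]
            )


def replay_stream(
    recording: Recording,
    paced: bool = False,
    sleep: Callable[[float], None] = time.sleep,
) -> Iterator[Sample]:
    """Yield a recording's samples in order, optionally at wall-clock pace.

    ``paced=True`` sleeps the inter-sample gap before each yield so the
    stream approximates real-time arrival; pacing never alters content.
    """
    prev_ts: float | None = None
    for s in recording.samples:
        if paced and prev_ts is not None:
            gap = s.timestamp - prev_ts
            if gap > 0:
                sleep(gap)
        prev_ts = s.timestamp
        yield s


def attach_arrival_timestamps(
    values: Iterable[Sequence[float]], clock: Callable[[], float]
) -> Iterator[Sample]:
    """Stamp unstamped channel-value tuples with the clock reading at arrival.

    Some headsets (the Muse via its phone bridge) deliver samples without
    timestamps; the pipeline stamps them on receipt.  The clock must be
    monotone non-decreasing; a regression raises.
    """
    prev: float | None = None
    for vals in values:
        now = float(clock())
        if prev is not None and now < prev:
            raise ValueError(f"clock regression: {now} < {prev}")
        prev = now
        yield Sample(now, tuple(float(v) for v in vals))


def read_label_stream(path) -> list[LabelTuple]:
    """Read a label CSV (``dimension,rating,t_start,t_end``) in arrival order.

    Tuples are returned ordered by ``t_end`` — the time each rating becomes
    available — with ties broken by the fixed dimension order so a video's
    arousal tuple precedes its valence tuple, as in the live protocol.
    """
    df = pd.read_csv(path)
    need = ["dimension", "rating", "t_start", "t_end"]
    if list(df.columns) != need and set(df.columns) != set(need):
        raise ValueError(f"{path}: expected columns {need}, got {list(df.columns)}")
    tuples = [
        LabelTuple(str(r.dimension), float(r.rating), float(r.t_start), float(r.t_end))
        for r in df.itertuples(index=False)
    ]
    tuples.sort(key=lambda t: (t.t_end, DIMENSIONS.index(t.dimension)))
    return tuples


def write_label_stream(tuples: Sequence[LabelTuple], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["dimension", "rating", "t_start", "t_end"])
        for t in tuples:
            w.writerow([t.dimension, f"{t.rating:.6f}", f"{t.t_start:.6f}", f"{t.t_end:.6f}"])
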