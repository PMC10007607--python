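"""Tumbling-window segmentation and band-power feature extraction.

The stream is cut into tumbling windows — fixed length ``l`` seconds,
no overlap, ``l * sf`` samples each — and every window is summarized by
16 spectral features per channel:

* power in the five classical EEG bands, Delta (0.5-4 Hz), Theta
  (4-8 Hz), Alpha (8-16 Hz), Beta (16-32 Hz) and Gamma (32-45 Hz),
  estimated by integrating a Welch PSD over each band;
* the total power over 0.5-45 Hz;
* the ten pairwise band-power ratios (unordered pairs in the fixed band
  order above).

A 4-channel headset therefore yields 64 features per window, an
8-channel one 128, a 14-channel one 224.

Band edges are half-open ``[low, high)`` over PSD bin centers, so the
five bands partition the 0.5-45 Hz range and their powers sum to the
total exactly.  Amplitude scaling ``x -> a x`` scales every power by
``a**2`` and leaves every ratio unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import signal as _sig

from .devices import DeviceProfile, Recording, Sample

__all__ = [
    "BANDS",
    "BAND_NAMES",
    "RATIO_PAIRS",
    "FEATURES_PER_CHANNEL",
    "WindowConfig",
    "Window",
    "FeatureVector",
    "tumbling_windows",
    "aligned_stimulus_intervals",
    "windows_in_stimulus",
    "stimulus_windows",
    "shuffle_labeled_windows",
    "welch_band_powers",
    "power_ratios",
    "extract_feature_vector",
    "feature_names",
    "write_feature_table",
]

# Band edges as used throughout: name -> (low, high) in Hz.  The Alpha
# band's 8-16 Hz upper edge is wider than the textbook 8-13 Hz; it is the
# convention this pipeline standardizes on.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 16.0),
    "beta": (16.0, 32.0),
    "gamma": (32.0, 45.0),
}
BAND_NAMES: tuple[str, ...] = tuple(BANDS)
TOTAL_RANGE: tuple[float, float] = (0.5, 45.0)
RATIO_PAIRS: tuple[tuple[int, int], ...] = tuple(combinations(range(5), 2))
FEATURES_PER_CHANNEL = len(BAND_NAMES) + 1 + len(RATIO_PAIRS)  # 5 + 1 + 10 = 16
RATIO_EPS = 1e-12


@dataclass(frozen=True)
class WindowConfig:
    """Tumbling-window sizing: ``length_l`` seconds at ``sf`` Hz."""

    length_l: float = 1.0
    sf: float = 256.0

    def __post_init__(self) -> None:
        n = self.length_l * self.sf
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"window length {self.length_l} s x {self.sf} Hz must give a "
                f"positive integer sample count, got {n}"
            )

    @property
    def n_samples(self) -> int:
        """Samples per window, |w| = l * sf."""
        return int(round(self.length_l * self.sf))


@dataclass
class Window:
    """One tumbling window: an (n_samples, n_channels) block with its time span."""

    data: np.ndarray
    t_start: float
    t_end: float


@dataclass
class FeatureVector:
    """Per-window feature vector, 16 features per channel, channels concatenated.

    ``labels`` optionally carries the binary class (0=low, 1=high) per
    affect dimension once label tuples have been matched.
    """

    values: np.ndarray
    t_start: float
    t_end: float
    labels: dict[str, int] | None = None

    def label(self, dimension: str) -> int | None:
        return None if self.labels is None else self.labels.get(dimension)


def tumbling_windows(
    stream: Iterable[Sample], cfg: WindowConfig
) -> Iterator[Window]:
    """Cut an ordered sample stream into consecutive non-overlapping windows.

    Each window holds exactly ``cfg.n_samples`` samples; a trailing partial
    block is discarded.  The window's ``t_start`` is its first sample's
    timestamp and ``t_end = t_start + l``.
    """
    n = cfg.n_samples
    buf: list[Sample] = []
    for s in stream:
        buf.append(s)
        if len(buf) == n:
            data = np.array([b.values for b in buf], dtype=float)
            t0 = buf[0].timestamp
            yield Window(data, t0, t0 + cfg.length_l)
            buf = []


def aligned_stimulus_intervals(
    t_start: float, t_end: float, length_l: float
) -> list[tuple[float, float]]:
    """Window intervals tiling backward from the stimulus end.

    Returns ``floor((t_end - t_start) / l)`` half-open intervals, the last
    one ending exactly at ``t_end``; a fractional leftover at the stimulus
    start is dropped.
    """
    if t_end <= t_start:
        return []
    k = int(np.floor((t_end - t_start) / length_l + 1e-9))
    return [(t_end - (i + 1) * length_l, t_end - i * length_l) for i in range(k)][::-1]


def windows_in_stimulus(
    windows: Sequence[Window], t_start: float, t_end: float
) -> list[Window]:
    """Keep pre-existing windows that lie wholly inside ``[t_start, t_end]``.

    This is the fallback when windows cannot be re-aligned to the stimulus
    end (e.g., features were already extracted on a free-running grid); the
    aligned alternative is :func:`stimulus_windows`.
    """
    if t_end <= t_start:
        return []
    return [w for w in windows if w.t_start >= t_start and w.t_end <= t_end]


def stimulus_windows(
    recording: Recording, t_start: float, t_end: float, cfg: WindowConfig
) -> list[Window]:
    """Tumbling windows aligned with the end of a stimulus interval.

    Tiles :func:`aligned_stimulus_intervals` backward from ``t_end`` and
    slices the recording's samples into them; intervals not fully covered
    by the recording are dropped.
    """
    ts = recording.timestamps()
    arr = recording.to_array()
    n = cfg.n_samples
    out: list[Window] = []
    for lo, hi in aligned_stimulus_intervals(t_start, t_end, cfg.length_l):
        i = int(np.searchsorted(ts, lo - 1e-9, side="left"))
        j = i + n
        if j > len(ts) or ts[i] >= hi:
            continue
        out.append(Window(arr[i:j], lo, hi))
    return out


def shuffle_labeled_windows(items: Sequence, seed: int) -> list:
    """Seeded uniform permutation of (window, label)-style items.

    Windows travel with their labels, so shuffling changes only the order
    in which the stream is presented, never the joint multiset.  Requires
    the full labeled set in memory — which is why the live protocol trains
    its initial model on a recorded block.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(items))
    return [items[i] for i in perm]


def welch_band_powers(
    window: np.ndarray,
    sf: float,
    bands: dict[str, tuple[float, float]] | None = None,
    nperseg: int | None = None,
) -> np.ndarray:
    """Per-channel band powers plus total power from a Welch PSD.

    Returns an array of shape (n_channels, n_bands + 1): the five band
    powers in fixed order followed by the total over 0.5-45 Hz.  The PSD
    uses Hann-tapered segments of ``min(window length, 1 s)`` with 50%
    overlap (so 1-s windows use a single full-length segment), density
    scaling; powers are the PSD summed over bins whose centers fall in
    the half-open band, times the bin width.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 2 or w.shape[0] == 0:
        raise ValueError(f"window must be a non-empty 2-D array, got shape {w.shape}")
    bands = bands or BANDS
    if nperseg is None:
        nperseg = min(w.shape[0], int(round(sf)))
    freqs, psd = _sig.welch(
        w, fs=sf, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        scaling="density", axis=0,
    )
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    out = np.empty((w.shape[1], len(bands) + 1))
    total_mask = (freqs >= TOTAL_RANGE[0]) & (freqs < TOTAL_RANGE[1])
    for c, (lo, hi) in enumerate(bands.values()):
        mask = (freqs >= lo) & (freqs < hi)
        out[:, c] = psd[mask].sum(axis=0) * df
    out[:, -1] = psd[total_mask].sum(axis=0) * df
    return out


def power_ratios(band_powers: np.ndarray) -> np.ndarray:
    """The ten pairwise band-power ratios per channel.

    For band powers ``(delta, theta, alpha, beta, gamma)`` the ratios are
    ``band_i / (band_j + eps)`` for all pairs ``i < j`` in that fixed
    order — C(5,2) = 10 values per channel.  The epsilon guards silent
    channels with zero power.
    """
    bp = np.atleast_2d(np.asarray(band_powers, dtype=float))
    if bp.shape[1] != 5:
        raise ValueError(f"expected 5 band powers per channel, got {bp.shape[1]}")
    if np.any(bp < 0):
        raise ValueError("band powers must be non-negative")
    cols = [bp[:, i] / (bp[:, j] + RATIO_EPS) for i, j in RATIO_PAIRS]
    return np.stack(cols, axis=1)


def extract_feature_vector(
    window: Window, profile: DeviceProfile, cfg: WindowConfig
) -> FeatureVector:
    """The full 16-per-channel feature vector for one preprocessed window.

    Per channel the order is the five band powers, the total power, then
    the ten ratios in pair order; channels are concatenated in profile
    order, giving ``16 * n_channels`` values.
    """
    if window.data.shape[1] != profile.n_channels:
        raise ValueError(
            f"window has {window.data.shape[1]} channels, profile "
            f"{profile.name!r} has {profile.n_channels}"
        )
    powers = welch_band_powers(window.data, cfg.sf)
    ratios = power_ratios(powers[:, :5])
    per_channel = np.concatenate([powers, ratios], axis=1)  # (C, 16)
    values = per_channel.reshape(-1)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite feature value (NaN/Inf in band powers)")
    return FeatureVector(values, window.t_start, window.t_end)


def feature_names(profile: DeviceProfile) -> list[str]:
    """Column names matching :func:`extract_feature_vector`'s layout."""
    names = []
    for ch in profile.channel_names:
        names.extend(f"{ch}_{b}" for b in BAND_NAMES)
        names.append(f"{ch}_total")
        names.extend(
            f"{ch}_ratio_{BAND_NAMES[i]}_{BAND_NAMES[j]}" for i, j in RATIO_PAIRS
        )
    return names


def write_feature_table(
    features: Sequence[FeatureVector], profile: DeviceProfile, path
) -> None:
    """Write features as CSV with one row per window.

    Columns: ``t_start``, ``t_end``, the per-channel feature columns, then
    ``label_valence`` and ``label_arousal`` (empty where unlabeled).
    """
    import csv

    cols = feature_names(profile)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t_start", "t_end", *cols, "label_valence", "label_arousal"])
        for f in features:
            lv, la = f.label("valence"), f.label("arousal")
            w.writerow(
                [f"{f.t_start:.6f}", f"{f.t_end:.6f}"]
                + [repr(v) for v in f.values]
                + ["" if lv is None else lv, "" if la is None else la]
            )
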