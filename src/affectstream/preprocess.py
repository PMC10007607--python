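"""Per-window EEG artifact removal.

Three minimal, stream-compatible steps, applied independently to each
tumbling window (no filter state crosses window boundaries, which keeps
windows causally independent):

1. second-order IIR notch at the mains frequency (50 Hz default) to remove
   power-line interference;
2. fifth-order Butterworth band-pass, 0.5-45 Hz, to remove DC drift and
   high-frequency noise;
3. common average reference (CAR): subtract the instantaneous mean across
   channels from every channel.

Filtering is causal (forward-only) by default because that is the only
variant realizable sample-by-sample in a live system; zero-phase
forward-backward filtering is available via ``zero_phase=True`` for
offline use.  Edge transients from per-window filtering are accepted as a
consequence of statelessness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "PreprocessConfig",
    "notch_filter",
    "bandpass_filter",
    "common_average_reference",
    "preprocess_window",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Configuration for the per-window cleaning chain."""

    notch_enabled: bool = True
    notch_f0: float = 50.0
    notch_q: float = 30.0
    bandpass_low: float = 0.5
    bandpass_high: float = 45.0
    bandpass_order: int = 5
    reference: str = "car"  # "car" | "none"
    zero_phase: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        notch = d.get("notch", {})
        bp = d.get("bandpass", {})
        return cls(
            notch_enabled=bool(notch.get("enabled", True)),
            notch_f0=float(notch.get("f0", 50.0)),
            notch_q=float(notch.get("q", 30.0)),
            bandpass_low=float(bp.get("low", 0.5)),
            bandpass_high=float(bp.get("high", 45.0)),
            bandpass_order=int(bp.get("order", 5)),
            reference=str(d.get("reference", "car")),
            zero_phase=bool(d.get("zero_phase", False)),
        )


def _as_window(window: np.ndarray) -> np.ndarray:
    w = np.asarray(window, dtype=float)
    if w.ndim != 2:
        raise ValueError(f"window must be 2-D (samples x channels), got shape {w.shape}")
    return w


def _apply(b: np.ndarray, a: np.ndarray, w: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        return signal.filtfilt(b, a, w, axis=0)
    return signal.lfilter(b, a, w, axis=0)


def notch_filter(
    window: np.ndarray,
    sf: float,
    f0: float = 50.0,
    q: float = 30.0,
    zero_phase: bool = False,
) -> np.ndarray:
    """Suppress a narrow band around ``f0`` with a second-order IIR notch.

    ``q`` is the quality factor (f0 / bandwidth); larger q means a narrower
    notch.  The passband away from ``f0`` is essentially untouched.
    """
    w = _as_window(window)
    if not 0 < f0 < sf / 2:
        raise ValueError(f"notch frequency {f0} Hz outside (0, Nyquist={sf / 2}) Hz")
    b, a = signal.iirnotch(f0, q, fs=sf)
    return _apply(b, a, w, zero_phase)


def bandpass_filter(
    window: np.ndarray,
    sf: float,
    low: float = 0.5,
    high: float = 45.0,
    order: int = 5,
    zero_phase: bool = False,
) -> np.ndarray:
    """Butterworth band-pass; removes DC drift and out-of-band noise."""
    w = _as_window(window)
    if not 0 < low < high < sf / 2:
        raise ValueError(f"invalid band edges ({low}, {high}) Hz at sf={sf} Hz")
    sos = signal.butter(order, (low, high), btype="bandpass", fs=sf, output="sos")
    if zero_phase:
        return signal.sosfiltfilt(sos, w, axis=0)
    return signal.sosfilt(sos, w, axis=0)


def common_average_reference(window: np.ndarray) -> np.ndarray:
    """Subtract the cross-channel mean from every channel, per sample.

    Re-references the montage to the instantaneous scalp average; after
    CAR every sample row sums to zero.  Undefined for a single channel.
    """
    w = _as_window(window)
    if w.shape[1] < 2:
        raise ValueError("common average reference needs at least 2 channels")
    return w - w.mean(axis=1, keepdims=True)


def preprocess_window(
    window: np.ndarray, sf: float, config: PreprocessConfig | None = None
) -> np.ndarray:
    """Run the full cleaning chain: notch, band-pass, then CAR."""
    cfg = config or PreprocessConfig()
    w = _as_window(window)
    if cfg.notch_enabled:
        w = notch_filter(w, sf, cfg.notch_f0, cfg.notch_q, cfg.zero_phase)
    w = bandpass_filter(
        w, sf, cfg.bandpass_low, cfg.bandpass_high, cfg.bandpass_order, cfg.zero_phase
    )
    if cfg.reference == "car":
        w = common_average_reference(w)
    elif cfg.reference != "none":
        raise ValueError(f"unknown reference mode {cfg.reference!r}")
    return w
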