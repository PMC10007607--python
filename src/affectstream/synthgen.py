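"""Seeded generator of device-realistic EEG sessions with known class
structure and delayed label streams.

The generator emulates the study design this pipeline targets: a subject
wearing a consumer EEG headset watches a balanced sequence of 16 short
emotional videos (durations drawn from a normal with mean 86.7 s and SD
27.8 s, clamped to 51-150 s, four videos per valence-arousal quadrant)
and reports one rating per affect dimension after each video, so labels
always arrive delayed by the stimulus length.

The signal model is deliberately simple and fully known:

* one sinusoid per classical EEG band at a seeded in-band frequency,
  with a per-channel random phase (so common-average referencing does
  not cancel it);
* the sinusoid's amplitude during a video is the band's baseline
  amplitude times a per-(dimension, class) multiplicative effect of that
  video's quadrant — the effect the pipeline is supposed to recover;
* 1/f (pink) background noise, seeded, per channel;
* mains interference at 50 Hz with slight per-channel amplitude spread
  (so the notch filter, not the reference, must remove it).

Ratings are emitted on the unit slider scale as the quadrant's nominal
value (high 0.75, low 0.25) plus clipped Gaussian noise; with the default
noise SD the 0.5 threshold recovers the intended class almost always,
injecting a small controllable label-noise rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .devices import (
    DeviceProfile,
    LabelTuple,
    Recording,
    Sample,
    builtin_profile,
    write_label_stream,
    write_recording,
)

__all__ = [
    "SynthConfig",
    "Stimulus",
    "StimulusSchedule",
    "SynthSession",
    "generate_schedule",
    "generate_session",
    "write_fixture_set",
    "QUADRANTS",
]

# quadrant -> (valence class, arousal class); 1 = high, 0 = low
QUADRANTS: dict[str, tuple[int, int]] = {
    "HAHV": (1, 1),
    "HALV": (0, 1),
    "LAHV": (1, 0),
    "LALV": (0, 0),
}

_NOMINAL_RATING = {0: 0.25, 1: 0.75}


def _default_band_amplitudes() -> dict[str, float]:
    # rough 1/f-flavored baseline oscillation amplitudes, microvolts
    return {"delta": 20.0, "theta": 12.0, "alpha": 15.0, "beta": 8.0, "gamma": 4.0}


def _default_class_effects() -> dict[str, dict[int, dict[str, float]]]:
    # valence expressed in the alpha band, arousal in the beta band;
    # multiplicative and symmetric on a log scale around the baseline
    return {
        "valence": {1: {"alpha": 1.6}, 0: {"alpha": 0.625}},
        "arousal": {1: {"beta": 1.6}, 0: {"beta": 0.625}},
    }


@dataclass
class SynthConfig:
    """Session-level knobs for the synthetic generator."""

    profile: DeviceProfile = field(default_factory=lambda: builtin_profile("muse_s"))
    n_videos: int = 16
    duration_mean: float = 86.7
    duration_sd: float = 27.8
    duration_range: tuple[float, float] = (51.0, 150.0)
    gap_range: tuple[float, float] = (15.0, 30.0)  # questionnaire time between videos
    lead_in: float = 10.0
    band_amplitudes: dict[str, float] = field(default_factory=_default_band_amplitudes)
    class_effects: dict[str, dict[int, dict[str, float]]] = field(
        default_factory=_default_class_effects
    )
    pink_noise_scale: float = 6.0  # microvolts RMS
    line_hz: float = 50.0
    line_amplitude: float = 12.0
    rating_noise_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_videos % 4 != 0:
            raise ValueError("n_videos must be divisible by 4 (quadrant balance)")
        if any(a < 0 for a in self.band_amplitudes.values()):
            raise ValueError("band amplitudes must be non-negative")


@dataclass(frozen=True)
class Stimulus:
    video_id: int
    quadrant: str
    t_start: float
    t_end: float


@dataclass
class StimulusSchedule:
    stimuli: list[Stimulus]

    def __post_init__(self) -> None:
        for a, b in zip(self.stimuli, self.stimuli[1:]):
            if b.t_start < a.t_end:
                raise ValueError("stimuli must be non-overlapping and increasing")

    def __len__(self) -> int:
        return len(self.stimuli)


@dataclass
class SynthSession:
    """A complete generated session: signal, delayed labels, and truth."""

    recording: Recording
    labels: list[LabelTuple]
    schedule: StimulusSchedule
    truth: list[dict]


def generate_schedule(cfg: SynthConfig) -> StimulusSchedule:
    """A balanced, seeded-random stimulus schedule.

    Each quadrant contributes ``n_videos / 4`` stimuli; the presentation
    order is a seeded permutation, durations are clamped normals, and
    consecutive videos are separated by a seeded questionnaire gap.
    """
    rng = np.random.default_rng((cfg.seed, 101))
    quadrants = [q for q in QUADRANTS for _ in range(cfg.n_videos // 4)]
    order = rng.permutation(len(quadrants))
    durations = np.clip(
        rng.normal(cfg.duration_mean, cfg.duration_sd, cfg.n_videos),
        *cfg.duration_range,
    )
    gaps = rng.uniform(*cfg.gap_range, cfg.n_videos)
    stimuli = []
    t = cfg.lead_in
    for i, idx in enumerate(order):
        t_start, t_end = t, t + float(durations[i])
        stimuli.append(Stimulus(video_id=i + 1, quadrant=quadrants[idx], t_start=t_start, t_end=t_end))
        t = t_end + float(gaps[i])
    return StimulusSchedule(stimuli)


def _pink_noise(rng: np.random.Generator, n: int, sf: float, rms: float) -> np.ndarray:
    """Spectrally shaped white noise with a 1/f amplitude profile."""
    freqs = np.fft.rfftfreq(n, d=1.0 / sf)
    spectrum = rng.normal(size=len(freqs)) + 1j * rng.normal(size=len(freqs))
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spectrum * shape, n=n)
    current = np.sqrt(np.mean(x**2))
    return x * (rms / current) if current > 0 else x


def generate_session(cfg: SynthConfig) -> SynthSession:
    """Generate one full synthetic session (recording + labels + truth)."""
    from .featurize import BANDS

    schedule = generate_schedule(cfg)
    rng = np.random.default_rng((cfg.seed, 202))
    sf = cfg.profile.sampling_rate
    n_ch = cfg.profile.n_channels
    t_total = schedule.stimuli[-1].t_end + 5.0
    n = int(round(t_total * sf))
    t = np.arange(n) / sf

    # per-band amplitude envelope over time: baseline outside stimuli,
    # baseline x valence effect x arousal effect inside
    envelopes = {b: np.full(n, amp) for b, amp in cfg.band_amplitudes.items()}
    for stim in schedule.stimuli:
        v_cls, a_cls = QUADRANTS[stim.quadrant]
        i0 = int(round(stim.t_start * sf))
        i1 = int(round(stim.t_end * sf))
        for band in envelopes:
            mult = cfg.class_effects.get("valence", {}).get(v_cls, {}).get(band, 1.0)
            mult *= cfg.class_effects.get("arousal", {}).get(a_cls, {}).get(band, 1.0)
            if mult != 1.0:
                envelopes[band][i0:i1] *= mult

    data = np.zeros((n, n_ch))
    for band, (lo, hi) in BANDS.items():
        freq = rng.uniform(lo + 0.2 * (hi - lo), hi - 0.2 * (hi - lo))
        phases = rng.uniform(0, 2 * np.pi, n_ch)
        carrier = 2 * np.pi * freq * t
        env = envelopes[band]
        for c in range(n_ch):
            data[:, c] += env * np.sin(carrier + phases[c])
    for c in range(n_ch):
        data[:, c] += _pink_noise(rng, n, sf, cfg.pink_noise_scale)
    if cfg.line_amplitude > 0:
        line_amps = cfg.line_amplitude * rng.uniform(0.8, 1.2, n_ch)
        line_phases = rng.uniform(0, 2 * np.pi, n_ch)
        carrier = 2 * np.pi * cfg.line_hz * t
        for c in range(n_ch):
            data[:, c] += line_amps[c] * np.sin(carrier + line_phases[c])

    samples = [Sample(float(ti), tuple(row)) for ti, row in zip(t, data)]
    recording = Recording(cfg.profile, samples)

    labels: list[LabelTuple] = []
    truth: list[dict] = []
    for stim in schedule.stimuli:
        v_cls, a_cls = QUADRANTS[stim.quadrant]
        entry = {
            "video_id": stim.video_id,
            "quadrant": stim.quadrant,
            "t_start": stim.t_start,
            "t_end": stim.t_end,
            "classes": {"valence": v_cls, "arousal": a_cls},
            "ratings": {},
        }
        for dim, cls in (("arousal", a_cls), ("valence", v_cls)):
            rating = float(
                np.clip(
                    _NOMINAL_RATING[cls] + rng.normal(0.0, cfg.rating_noise_sd),
                    0.0,
                    1.0,
                )
            )
            labels.append(LabelTuple(dim, rating, stim.t_start, stim.t_end))
            entry["ratings"][dim] = rating
        truth.append(entry)
    return SynthSession(recording, labels, schedule, truth)


def write_fixture_set(cfg: SynthConfig, out_dir) -> dict[str, Path]:
    """Write one synthetic subject to disk: recording CSV, label CSV, and a
    ground-truth JSON.  Deterministic from the config's seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session = generate_session(cfg)
    paths = {
        "recording": out / "recording.csv",
        "labels": out / "labels.csv",
        "truth": out / "truth.json",
    }
    write_recording(session.recording, paths["recording"])
    write_label_stream(session.labels, paths["labels"])
    manifest = {
        "profile": cfg.profile.name,
        "seed": cfg.seed,
        "n_videos": cfg.n_videos,
        "videos": session.truth,
    }
    paths["truth"].write_text(json.dumps(manifest, indent=2))
    return paths
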