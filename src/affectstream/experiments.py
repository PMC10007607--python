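"""End-to-end experiment runners behind the command-line interface.

Three settings mirror how the pipeline is used:

* **immediate** — preprocess, window (aligned with each stimulus end),
  featurize, label, shuffle, then k seeded shuffle-repeats of a full
  test-then-train run per affect dimension;
* **window sweep** — the immediate setting at window lengths 1-5 s to
  locate the best-performing length;
* **delayed / live** — part 1 of a session trains an initial model on
  shuffled windows; part 2 replays in time order with labels arriving at
  stimulus end (or after a fixed induced lag), evaluated by delayed
  progressive validation resuming from the part-1 model.

Everything is an event-time simulation in a single process: wall-clock
pacing is available in the replay layer but never affects results.  Each
run writes a JSON metadata record (config, seeds, versions) sufficient to
reproduce it bit-for-bit for deterministic learners.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .devices import DeviceProfile, LabelTuple, Recording, builtin_profile, read_label_stream, read_recording
from .evaluate import (
    MetricTrajectory,
    RepeatSummary,
    delayed_progressive_validate,
    metrics_from_pairs,
    progressive_validate,
    shuffled_repeats,
)
from .featurize import (
    FeatureVector,
    Window,
    WindowConfig,
    extract_feature_vector,
    shuffle_labeled_windows,
    stimulus_windows,
)
from .labels import assign_labels
from .learners import LearnerConfig, make_classifier
from .preprocess import PreprocessConfig, preprocess_window
from .synthgen import SynthConfig, SynthSession, generate_session

__all__ = [
    "ExperimentConfig",
    "session_features",
    "run_immediate",
    "run_window_sweep",
    "run_delayed",
    "load_config",
]

DIMENSIONS = ("valence", "arousal")


@dataclass
class ExperimentConfig:
    """Validated experiment configuration (see the YAML schema in the CLI)."""

    device: str = "muse_s"
    seed: int = 0
    window_length: float = 1.0
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    learner: LearnerConfig = dataclasses.field(default_factory=LearnerConfig)
    repeats: int = 10
    dimensions: tuple[str, ...] = DIMENSIONS
    synth_overrides: dict = dataclasses.field(default_factory=dict)
    recording_path: str | None = None
    labels_path: str | None = None
    delay_windows: int = 86
    split_after_video: int | None = None  # part-1/part-2 boundary (delayed runs)

    @property
    def profile(self) -> DeviceProfile:
        return builtin_profile(self.device)


def load_config(d: dict) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a parsed YAML/JSON mapping."""
    learner = d.get("learner", {})
    evaluation = d.get("evaluation", {})
    delayed = d.get("delayed", {})
    inputs = d.get("inputs", {})
    return ExperimentConfig(
        device=str(d.get("device", "muse_s")),
        seed=int(d.get("seed", 0)),
        window_length=float(d.get("window", {}).get("length_l", 1.0)),
        preprocess=PreprocessConfig.from_dict(d.get("preprocess", {})),
        learner=LearnerConfig(
            kind=str(learner.get("kind", "arf")),
            n_trees=int(learner.get("n_trees", 5)),
            learning_rate=float(learner.get("learning_rate", 0.1)),
            seed=int(learner.get("seed", d.get("seed", 0))),
        ),
        repeats=int(evaluation.get("repeats", 10)),
        dimensions=tuple(evaluation.get("dimensions", DIMENSIONS)),
        synth_overrides=dict(d.get("synth", {})),
        recording_path=inputs.get("recording"),
        labels_path=inputs.get("labels"),
        delay_windows=int(delayed.get("delay_windows", 86)),
        split_after_video=delayed.get("split_after_video"),
    )


def _synth_config(cfg: ExperimentConfig) -> SynthConfig:
    overrides = dict(cfg.synth_overrides)
    overrides.setdefault("seed", cfg.seed)
    return SynthConfig(profile=cfg.profile, **overrides)


def _load_inputs(cfg: ExperimentConfig) -> tuple[Recording, list[LabelTuple], SynthSession | None]:
    if cfg.recording_path and cfg.labels_path:
        rec = read_recording(cfg.recording_path, cfg.profile)
        return rec, read_label_stream(cfg.labels_path), None
    session = generate_session(_synth_config(cfg))
    return session.recording, session.labels, session


def stimulus_intervals(tuples: Sequence[LabelTuple]) -> list[tuple[float, float]]:
    """Distinct stimulus intervals, recovered from the label stream."""
    return sorted({(t.t_start, t.t_end) for t in tuples})


def session_features(
    recording: Recording,
    tuples: Sequence[LabelTuple],
    window_cfg: WindowConfig,
    pre_cfg: PreprocessConfig,
) -> list[FeatureVector]:
    """Labeled feature vectors for every stimulus in a session.

    Windows are aligned with each stimulus's end, preprocessed per window,
    featurized, and labeled by interval matching against the label stream.
    """
    profile = recording.profile
    feats: list[FeatureVector] = []
    for t0, t1 in stimulus_intervals(tuples):
        for w in stimulus_windows(recording, t0, t1, window_cfg):
            cleaned = preprocess_window(w.data, window_cfg.sf, pre_cfg)
            feats.append(
                extract_feature_vector(Window(cleaned, w.t_start, w.t_end), profile, window_cfg)
            )
    return assign_labels(feats, tuples)


def _run_metadata(cfg: ExperimentConfig, extra: dict | None = None) -> dict:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    meta = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": json.loads(blob),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    if extra:
        meta.update(extra)
    return meta


def _write_json(path: Path, payload: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, default=str))


def _summary_dict(s: RepeatSummary) -> dict:
    return {
        "mean_macro_f1": s.mean_macro_f1,
        "sd_macro_f1": s.sd_macro_f1,
        "mean_accuracy": s.mean_accuracy,
        "sd_accuracy": s.sd_accuracy,
        "per_repeat": [
            {"macro_f1": p.macro_f1, "accuracy": p.accuracy, "f1_high": p.f1_high, "f1_low": p.f1_low}
            for p in s.per_repeat
        ],
    }


def run_immediate(cfg: ExperimentConfig, out_dir=None) -> dict:
    """The immediate-label setting: shuffle-repeat prequential evaluation.

    Returns (and optionally writes) per-dimension mean/SD of final macro
    F1 and accuracy over ``cfg.repeats`` seeded shuffles.
    """
    recording, tuples, _ = _load_inputs(cfg)
    wcfg = WindowConfig(cfg.window_length, cfg.profile.sampling_rate)
    feats = session_features(recording, tuples, wcfg, cfg.preprocess)
    results: dict = {"setting": "immediate", "n_windows": len(feats), "dimensions": {}}
    for dim in cfg.dimensions:
        labeled = [f for f in feats if f.label(dim) is not None]

        def factory(seed: int, _dim=dim) -> object:
            return make_classifier(
                dataclasses.replace(cfg.learner, seed=seed), len(labeled[0].values)
            )

        summary = shuffled_repeats(
            labeled, factory, dim, k=cfg.repeats, base_seed=cfg.seed
        )
        results["dimensions"][dim] = _summary_dict(summary)
    if out_dir is not None:
        out = Path(out_dir)
        _write_json(out / "metrics.json", results)
        _write_json(out / "run_meta.json", _run_metadata(cfg))
    return results


def run_window_sweep(
    cfg: ExperimentConfig, lengths: Sequence[float] = (1, 2, 3, 4, 5), out_dir=None
) -> dict:
    """The immediate setting swept over window lengths.

    One row per (length, dimension); the report flags whether the 1-s
    window attains the best mean macro F1 per dimension (the trend the
    full-scale studies show), without asserting it.
    """
    rows = []
    for l in lengths:
        sub = dataclasses.replace(cfg, window_length=float(l))
        res = run_immediate(sub)
        for dim, summary in res["dimensions"].items():
            rows.append(
                {
                    "window_length": float(l),
                    "dimension": dim,
                    "classifier": cfg.learner.kind,
                    "n_windows": res["n_windows"],
                    "mean_macro_f1": summary["mean_macro_f1"],
                    "sd_macro_f1": summary["sd_macro_f1"],
                    "mean_accuracy": summary["mean_accuracy"],
                }
            )
    best_at_1s = {}
    for dim in cfg.dimensions:
        dim_rows = [r for r in rows if r["dimension"] == dim]
        best = max(dim_rows, key=lambda r: r["mean_macro_f1"])
        best_at_1s[dim] = best["window_length"] == 1.0
    results = {"setting": "window_sweep", "rows": rows, "one_second_is_best": best_at_1s}
    if out_dir is not None:
        out = Path(out_dir)
        _write_json(out / "sweep.json", results)
        _write_json(out / "run_meta.json", _run_metadata(cfg))
    return results


def _induced_delay_labels(
    labeled: Sequence[FeatureVector], dimension: str, delay_s: float
) -> list[tuple[float, LabelTuple]]:
    """Per-window label tuples whose arrival lags the window by ``delay_s``."""
    out = []
    for fv in labeled:
        y = fv.label(dimension)
        rating = 1.0 if y == 1 else 0.0
        out.append(
            (fv.t_end + delay_s, LabelTuple(dimension, rating, fv.t_start, fv.t_end))
        )
    return out


def run_delayed(cfg: ExperimentConfig, out_dir=None, induced: bool | None = None) -> dict:
    """The delayed-label / live setting.

    Two modes:

    * **two-part live protocol** (``induced=False``): the first
      ``split_after_video`` stimuli are the recorded part 1 — their
      shuffled windows train the initial model progressively — and the
      remaining stimuli replay in time order with each stimulus's label
      arriving at its end, evaluated by delayed progressive validation
      resuming from the part-1 model.
    * **induced delay** (``induced=True``): the whole session replays in
      time order and every window's true label arrives a fixed
      ``cfg.delay_windows`` windows late, emulating a constant label lag
      on an otherwise immediate-label session.
    """
    recording, tuples, _ = _load_inputs(cfg)
    wcfg = WindowConfig(cfg.window_length, cfg.profile.sampling_rate)
    feats = session_features(recording, tuples, wcfg, cfg.preprocess)
    if induced is None:
        induced = cfg.split_after_video is None
    results: dict = {
        "setting": "delayed_induced" if induced else "delayed_live",
        "n_windows": len(feats),
        "dimensions": {},
    }
    logs: dict[str, MetricTrajectory] = {}
    for dim in cfg.dimensions:
        labeled = [f for f in feats if f.label(dim) is not None]
        labeled.sort(key=lambda f: f.t_start)
        n_features = len(labeled[0].values)
        clf = make_classifier(cfg.learner, n_features)
        if induced:
            delay_s = cfg.delay_windows * cfg.window_length
            label_events = _induced_delay_labels(labeled, dim, delay_s)
            traj = delayed_progressive_validate(labeled, label_events, clf, dim)
        else:
            split = cfg.split_after_video or 8
            intervals = stimulus_intervals(tuples)
            if split >= len(intervals):
                raise ValueError(
                    f"split_after_video={split} leaves no part-2 stimuli "
                    f"({len(intervals)} total)"
                )
            t_split = intervals[split - 1][1]
            part1 = [f for f in labeled if f.t_end <= t_split + 1e-9]
            part2 = [f for f in labeled if f.t_end > t_split + 1e-9]
            part1_order = shuffle_labeled_windows(part1, cfg.seed)
            progressive_validate(part1_order, clf, dim)  # initial model training
            part2_tuples = [
                t for t in tuples if t.dimension == dim and t.t_start > t_split - 1e-9
            ]
            traj = delayed_progressive_validate(part2, part2_tuples, clf, dim)
        logs[dim] = traj
        final = traj.final
        results["dimensions"][dim] = {
            "n_scored": len(traj.records),
            "final": None
            if final is None
            else {
                "accuracy": final.accuracy,
                "f1_high": final.f1_high,
                "f1_low": final.f1_low,
                "macro_f1": final.macro_f1,
            },
            "confusion": {
                "tp": traj.counts.tp,
                "tn": traj.counts.tn,
                "fp": traj.counts.fp,
                "fn": traj.counts.fn,
            },
        }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_json(out / "metrics.json", results)
        _write_json(out / "run_meta.json", _run_metadata(cfg))
        import csv

        with open(out / "predictions.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["t_start", "t_end", "dimension", "predicted", "score", "true", "scored_at"])
            for dim, traj in logs.items():
                for r in traj.records:
                    w.writerow(
                        [f"{r.t_start:.6f}", f"{r.t_end:.6f}", dim, r.predicted,
                         f"{r.score:.6f}", r.true, f"{r.scored_at:.6f}"]
                    )
    return results
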