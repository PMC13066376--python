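"""End-to-end experiment: simulate -> filter -> window -> featurize ->
train -> evaluate, per subject, with a closing paired t-test.

One master seed drives every stochastic stage; re-running the same config
reproduces the same report (timestamps aside).  Each subject gets its own
MEET model and its own gate-family Extra-Trees baseline, both scored on
the held-out fraction of a shared stratified split; the t-test compares
the per-subject accuracy pairs of the two models.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import meet
from .errors import ConfigurationError
from .evaluation import (
    MetricsReport,
    TTestResult,
    confusion,
    metrics,
    paired_t_test,
    stratified_split,
)
from .features import FeatureMatrix, FeatureParams, featurize
from .preprocess import FilterSpec, bandpass_filter, notch_filter, segment_windows
from .recording import write_recording
from .synth import ClassSignature, SynthConfig, generate_recording

log = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment", "load_config"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class ExperimentConfig:
    """Single source of truth for a reproducible experiment."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    bandpass: FilterSpec = field(default_factory=lambda: FilterSpec(kind="bandpass"))
    notch: FilterSpec = field(default_factory=lambda: FilterSpec(kind="notch"))
    window_ms: float = 256.0
    overlap_fraction: float = 0.25
    features: FeatureParams = field(default_factory=FeatureParams)
    a: int = 2
    hyperparams: dict = field(default_factory=dict)
    split: float = 0.7
    average: str = "macro"
    seed: int = 0
    workdir: str = "meet_experiment"
    save_recordings: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.split < 1:
            raise ConfigurationError("split must lie strictly in (0, 1)")
        # the master seed also drives the generator
        self.synth = dataclasses.replace(self.synth, seed=self.seed)

    def to_dict(self) -> dict:
        d = {
            "synth": self.synth.to_dict(),
            "bandpass": dataclasses.asdict(self.bandpass),
            "notch": dataclasses.asdict(self.notch),
            "window_ms": self.window_ms,
            "overlap_fraction": self.overlap_fraction,
            "features": dataclasses.asdict(self.features),
            "a": self.a,
            "hyperparams": self.hyperparams,
            "split": self.split,
            "average": self.average,
            "seed": self.seed,
            "workdir": self.workdir,
            "save_recordings": self.save_recordings,
        }
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path, **overrides) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a YAML/JSON file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides)
    synth_raw = raw.pop("synth", {})
    if "class_signatures" in synth_raw and synth_raw["class_signatures"] is not None:
        synth_raw["class_signatures"] = tuple(
            ClassSignature(**s) for s in synth_raw["class_signatures"]
        )
    if "burst_period_s" in synth_raw:
        synth_raw["burst_period_s"] = tuple(synth_raw["burst_period_s"])
    band_raw = raw.pop("bandpass", {})
    band_raw.pop("kind", None)
    notch_raw = raw.pop("notch", {})
    notch_raw.pop("kind", None)
    cfg = ExperimentConfig(
        synth=SynthConfig(**synth_raw),
        bandpass=FilterSpec(kind="bandpass", **band_raw),
        notch=FilterSpec(kind="notch", **notch_raw),
        features=FeatureParams(**raw.pop("features", {})),
        **raw,
    )
    return cfg


@dataclass
class ExperimentReport:
    """Everything an experiment produced, plus provenance to rerun it."""

    per_subject: dict[str, dict[str, MetricsReport]]
    meet_accuracies: list[float]
    baseline_accuracies: list[float]
    t_test: TTestResult | None
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "per_subject": {
                subj: {name: rep.to_dict() for name, rep in reps.items()}
                for subj, reps in self.per_subject.items()
            },
            "meet_accuracies": self.meet_accuracies,
            "baseline_accuracies": self.baseline_accuracies,
            "t_test": self.t_test.to_dict() if self.t_test else None,
            "provenance": self.provenance,
        }

    def to_json(self, include_timestamp: bool = True) -> str:
        d = self.to_dict()
        if not include_timestamp:
            d["provenance"] = {
                k: v for k, v in d["provenance"].items() if k != "timestamp"
            }
        return json.dumps(d, indent=2, sort_keys=True)


def _subject_features(config: ExperimentConfig, subject_index: int, workdir: Path) -> FeatureMatrix:
    rec = generate_recording(config.synth, subject_index)
    log.info("subject %s: generated %d samples x %d channels",
             rec.subject_id, rec.n_samples, rec.n_channels)
    if config.save_recordings:
        write_recording(rec, workdir / f"{rec.subject_id}_raw.csv")
    rec = bandpass_filter(rec, config.bandpass)
    rec = notch_filter(rec, config.notch)
    ws = segment_windows(rec, config.window_ms, config.overlap_fraction)
    log.info("subject %s: %d windows of %d samples (step %d)",
             rec.subject_id, len(ws), ws.window_len, ws.step)
    fm = featurize(ws, config.features)
    fm.to_dataframe().to_csv(workdir / f"{rec.subject_id}_features.csv", index=False)
    return fm


def _evaluate_subject(
    config: ExperimentConfig, fm: FeatureMatrix
) -> dict[str, MetricsReport]:
    train_idx, test_idx = stratified_split(fm, config.split, config.seed)
    X_tr, y_tr = fm.values[train_idx], fm.labels[train_idx]
    X_te, y_te = fm.values[test_idx], fm.labels[test_idx]
    class_order = tuple(int(c) for c in np.unique(fm.labels))

    model = meet.fit(X_tr, a=config.a, hyperparams=config.hyperparams,
                     seed=config.seed, labels=y_tr)
    meet_pred = meet.predict(model, X_te)

    baseline = meet._seeded_tree_ensemble(
        dict(meet.DEFAULT_HYPERPARAMS, **config.hyperparams), [config.seed, 2]
    )
    baseline.fit(X_tr, y_tr)
    et_pred = baseline.predict(X_te)

    return {
        "meet": metrics(confusion(y_te, meet_pred, class_order), config.average),
        "et": metrics(confusion(y_te, et_pred, class_order), config.average),
    }


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run the full per-subject workflow and write the report to workdir."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    per_subject: dict[str, dict[str, MetricsReport]] = {}
    meet_acc: list[float] = []
    et_acc: list[float] = []
    for subject_index in range(config.synth.n_subjects):
        subject_id = f"S{subject_index + 1:02d}"
        try:
            fm = _subject_features(config, subject_index, workdir)
            reports = _evaluate_subject(config, fm)
        except Exception as exc:
            raise RuntimeError(
                f"experiment failed at subject {subject_id}: {exc}"
            ) from exc
        per_subject[subject_id] = reports
        meet_acc.append(reports["meet"].accuracy)
        et_acc.append(reports["et"].accuracy)
        log.info("subject %s: MEET %.4f vs ET %.4f",
                 subject_id, reports["meet"].accuracy, reports["et"].accuracy)

    t_test = None
    if len(meet_acc) >= 2 and np.std(np.subtract(meet_acc, et_acc), ddof=1) > 0:
        t_test = paired_t_test(meet_acc, et_acc, pair_labels=("meet", "et"))

    report = ExperimentReport(
        per_subject=per_subject,
        meet_accuracies=meet_acc,
        baseline_accuracies=et_acc,
        t_test=t_test,
        provenance={
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "schema_version": REPORT_SCHEMA_VERSION,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
    )
    (workdir / "report.json").write_text(report.to_json())
    (workdir / "metrics.json").write_text(report.to_json(include_timestamp=False))
    return report
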