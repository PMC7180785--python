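"""End-to-end orchestration: data -> preprocess -> features -> labels ->
screening -> classification -> report artifacts.

A run is described by a :class:`PipelineConfig` (built in code or from a
YAML/JSON mapping) naming exactly one data source — the synthetic cohort
generator or CSV files on disk — and is fully reproducible: identical
configs produce byte-identical artifacts, and the emitted
:class:`RunManifest` records the config snapshot, seeds and artifact
checksums needed to replay it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .classification import ClassifierSpec, CVConfig
from .features import feature_matrix
from .io import (
    ParticipantRecord,
    read_eeg_csv,
    read_participants_csv,
    write_participants_csv,
)
from .labeling import (
    assign_pss_labels,
    build_ground_truth,
    compute_thresholds,
    label_counts,
)
from .model import StressClassificationModel
from .preprocessing import remove_dc_offset
from .selection import screening_report
from .simulate import GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs.

    Exactly one of ``synthetic`` / ``csv_participants`` must be set;
    ``csv_recordings_dir`` (files named ``<id>.csv``) enables the
    feature stages for a CSV source.
    """

    synthetic: Optional[GeneratorConfig] = None
    csv_participants: Optional[str] = None
    csv_recordings_dir: Optional[str] = None
    labeling_mode: str = "expert"
    selection_alpha: float = 0.05
    cv: CVConfig = field(default_factory=CVConfig)
    classifiers: tuple[str, ...] = ("SVM", "NB", "KNN", "LR", "MLP")
    output_dir: str = "eegstress-run"
    stages: str = "all"  # "all" or "label"
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.synthetic is None) == (self.csv_participants is None):
            raise ValueError("config must name exactly one data source")
        if not 0 < self.selection_alpha <= 1:
            raise ValueError(f"selection_alpha must be in (0, 1], got {self.selection_alpha}")
        if self.labeling_mode not in ("pss", "expert"):
            raise ValueError(f"labeling_mode must be pss or expert")
        if self.stages not in ("all", "label"):
            raise ValueError(f"stages must be 'all' or 'label', got {self.stages!r}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        mapping = dict(mapping)
        if "synthetic" in mapping and mapping["synthetic"] is not None:
            syn = dict(mapping["synthetic"])
            if "dc_offset_range" in syn:
                syn["dc_offset_range"] = tuple(syn["dc_offset_range"])
            mapping["synthetic"] = GeneratorConfig(**syn)
        if "cv" in mapping and mapping["cv"] is not None:
            mapping["cv"] = CVConfig(**dict(mapping["cv"]))
        if "classifiers" in mapping:
            mapping["classifiers"] = tuple(mapping["classifiers"])
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            return cls.from_mapping(yaml.safe_load(handle))


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seeds: dict
    artifacts: dict  # name -> {"path": ..., "sha256": ...}
    counts: dict
    timings: dict
    completed: bool = True

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_snapshot(config: PipelineConfig) -> dict:
    def _clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: _clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        return obj

    return _clean(config)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages and write all report artifacts.

    Artifacts (CSV unless noted): ``participants.csv`` with both label
    columns, ``features.csv`` (45 columns), ``screening.csv`` (tidy) and
    ``screening_report.csv`` (channels x bands p-value layout),
    ``accuracy.csv`` (subset x classifier grid), ``metrics.csv`` and
    ``manifest.json``.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, dict] = {}
    counts: dict[str, int] = {}
    timings: dict[str, float] = {}

    def _register(name: str, path: Path) -> None:
        artifacts[name] = {"path": str(path), "sha256": _sha256(path)}

    # --- stage: data -----------------------------------------------------
    tic = time.perf_counter()
    recordings = None
    if config.synthetic is not None:
        cohort = generate_cohort(config.synthetic)
        records = cohort.participants
        recordings = cohort.recordings
        seeds = {"master": config.synthetic.seed, "cv": config.cv.seed}
    else:
        records = read_participants_csv(config.csv_participants)
        seeds = {"cv": config.cv.seed}
        if config.csv_recordings_dir is not None:
            rec_dir = Path(config.csv_recordings_dir)
            recordings = {
                r.id: read_eeg_csv(rec_dir / f"{r.id}.csv", participant_id=r.id)
                for r in records
            }
    counts["participants"] = len(records)
    timings["data"] = time.perf_counter() - tic

    # --- stage: labeling -------------------------------------------------
    tic = time.perf_counter()
    thresholds = compute_thresholds([r.pss_score for r in records])
    pss = assign_pss_labels(records, thresholds)
    for r in records:
        r.pss_label = pss[r.id]
    pss_counts = label_counts(pss.values())
    logger.info(
        "PSS labeling: thresholds (%.3f, %.3f); counts %s",
        thresholds.t_low, thresholds.t_high, pss_counts,
    )
    counts.update({f"pss_{k}": v for k, v in pss_counts.items()})
    if any(r.expert_label is not None for r in records):
        expert_counts = label_counts(
            r.expert_label for r in records if r.expert_label is not None
        )
        counts.update({f"expert_{k}": v for k, v in expert_counts.items()})
        logger.info("expert labels: counts %s", expert_counts)
    path = write_participants_csv(records, out / "participants.csv")
    _register("participants", path)
    timings["labeling"] = time.perf_counter() - tic

    completed = True
    if config.stages == "all" and recordings is not None:
        # --- stage: features ---------------------------------------------
        tic = time.perf_counter()
        cleaned = {pid: remove_dc_offset(rec)[0] for pid, rec in recordings.items()}
        features = feature_matrix(cleaned)
        features.to_csv(out / "features.csv")
        _register("features", out / "features.csv")
        timings["features"] = time.perf_counter() - tic

        # --- stage: screening + classification via the model --------------
        tic = time.perf_counter()
        ids, labels = build_ground_truth(records, mode=config.labeling_mode)
        counts["classified_participants"] = len(ids)
        counts["stress_class"] = int(labels.sum())
        if len(ids) and len(np.unique(labels)) == 2:
            model = StressClassificationModel(
                features.loc[ids],
                labels,
                alpha=config.selection_alpha,
                specs=[ClassifierSpec.default(k) for k in config.classifiers],
                cv=config.cv,
            )
            results = model.fit()
            counts["selected_features"] = len(results.selected)
            logger.info(
                "screening (%s labels): %d/%d features selected at alpha=%s",
                config.labeling_mode, len(results.selected),
                features.shape[1], config.selection_alpha,
            )
            results.screening.to_csv(out / "screening.csv")
            _register("screening", out / "screening.csv")
            screening_report(results.screening_results).to_csv(
                out / "screening_report.csv"
            )
            _register("screening_report", out / "screening_report.csv")
            results.accuracy_table.to_csv(out / "accuracy.csv")
            _register("accuracy", out / "accuracy.csv")
            results.metrics.to_csv(out / "metrics.csv", index=False)
            _register("metrics", out / "metrics.csv")
            (out / "summary.txt").write_text(results.summary() + "\n")
            _register("summary", out / "summary.txt")
        else:
            logger.warning("classification skipped: ground truth lacks two classes")
            completed = False
        timings["analysis"] = time.perf_counter() - tic
    elif config.stages == "all":
        logger.warning("feature stages skipped: no recordings in the data source")
        completed = False

    manifest = RunManifest(
        config=_config_snapshot(config),
        seeds=seeds,
        artifacts=artifacts,
        counts=counts,
        timings=timings,
        completed=completed,
    )
    manifest.write(out / "manifest.json")
    return manifest
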