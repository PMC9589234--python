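"""End-to-end orchestration: synth -> preprocess -> featurize -> train ->
evaluate -> correlate, from one config and one master seed.

Per-stage seeds are derived from the master seed by hashing the stage
name, so a single integer fully determines every artifact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import featuremap, preprocess, stats
from .cnn import CNNConfig
from .evaluation import evaluate_task
from .recording import read_edf
from .synth import GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """One config for the whole pipeline."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    seed: int = 0
    band_low: float = preprocess.DEFAULT_BAND[0]
    band_high: float = preprocess.DEFAULT_BAND[1]
    notch: float = preprocess.DEFAULT_NOTCH
    epoch_len_s: float = preprocess.DEFAULT_EPOCH_S
    threshold_uv: float = preprocess.DEFAULT_THRESHOLD_UV
    min_effective: float = preprocess.DEFAULT_MIN_EFFECTIVE
    run_ica: bool = True
    window_s: float = featuremap.DEFAULT_WINDOW_S
    image_size: int = featuremap.DEFAULT_IMAGE_SIZE
    clip_uv: float = featuremap.DEFAULT_CLIP_UV
    split_unit: str = "image"
    n_folds: int = 10
    tasks: tuple[str, ...] = ("diagnosis", "severity")

    def __post_init__(self) -> None:
        if isinstance(self.generator, dict):
            self.generator = GeneratorConfig(**self.generator)
        if isinstance(self.cnn, dict):
            self.cnn = CNNConfig(**self.cnn)
        self.tasks = tuple(self.tasks)
        if not 0.0 <= self.min_effective <= 1.0:
            raise ValueError(
                f"min_effective must lie in [0, 1], got {self.min_effective}"
            )
        if self.split_unit not in ("image", "subject"):
            raise ValueError(f"unknown split unit {self.split_unit!r}")

    @classmethod
    def demo(cls, seed: int = 0) -> "PipelineConfig":
        """Reduced configuration that runs in minutes on one CPU."""
        return cls(
            generator=GeneratorConfig(
                n_healthy=6, n_nonmajor=4, n_major=4,
                duration_s=120.0, artifact_epoch_frac=0.05,
                bad_channel_prob=0.0, seed=seed,
            ),
            cnn=CNNConfig.reduced(seed=seed),
            seed=seed,
            image_size=100,
            n_folds=2,
            split_unit="subject",
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)

        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [enc(v) for v in obj]
            return obj

        path.write_text(yaml.safe_dump(enc(self), sort_keys=False))
        return path


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage in order; returns the summary dict.

    Artifacts land under ``out_dir``: raw/ (EDF + roster), clean/
    (EDF + screening report), maps/ (PNG + manifest), models/ and
    reports/ (metrics, scores, correlations, summary.json).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    summary: dict = {"seed": config.seed, "stages": {}}

    # synth
    gen = dataclasses.replace(
        config.generator, seed=stage_seed(config.seed, "synth")
    )
    raw_dir = out_dir / "raw"
    paths, roster = generate_cohort(gen, raw_dir)
    summary["stages"]["synth"] = {"n_subjects": len(roster), "n_edf": len(paths)}
    logger.info("synth: %d subjects", len(roster))

    # preprocess
    clean_dir = out_dir / "clean"
    clean_dir.mkdir(exist_ok=True)
    pp_seed = stage_seed(config.seed, "preprocess")
    reports = []
    effective = {}
    for p in sorted(paths):
        rec = read_edf(p)
        res = preprocess.preprocess_recording(
            rec,
            seed=pp_seed,
            low=config.band_low,
            high=config.band_high,
            notch=config.notch,
            epoch_len_s=config.epoch_len_s,
            threshold_uv=config.threshold_uv,
            min_effective=config.min_effective,
            run_ica=config.run_ica,
        )
        reports.append(res.report.to_row())
        if res.effective is not None:
            from .recording import write_edf

            write_edf(res.effective, clean_dir / f"{rec.subject_id}.edf")
            effective[rec.subject_id] = res.effective
    screening = pd.DataFrame(reports)
    screening.to_csv(clean_dir / "screening.csv", index=False)
    summary["stages"]["preprocess"] = {
        "n_included": int(screening["included"].sum()),
        "n_total": len(screening),
        "inclusion_rate": float(screening["included"].mean()),
    }

    # featurize
    maps_dir = out_dir / "maps"
    groups = dict(zip(roster["subject_id"], roster["group"]))
    manifest = featuremap.featurize_cohort(
        list(effective.values()), groups, maps_dir,
        win_s=config.window_s, size=config.image_size, clip_uv=config.clip_uv,
    )
    summary["stages"]["featurize"] = {
        "n_images": len(manifest),
        "per_group": {
            k: int(v) for k, v in manifest["group"].value_counts().items()
        },
    }

    # train + evaluate per task
    reports_dir = out_dir / "reports"
    reports_dir.mkdir(exist_ok=True)
    images = featuremap.load_manifest_images(manifest)
    pooled_by_task = {}
    for task in config.tasks:
        sub, labels = _task_classes(manifest, task)
        if np.unique(labels).size < 2:
            logger.warning("task %s skipped: only one class present", task)
            continue
        report, pooled = evaluate_task(
            manifest, images, task,
            config.cnn,
            seed=stage_seed(config.seed, f"eval-{task}"),
            unit=config.split_unit,
            n_folds=config.n_folds,
        )
        report.to_json(reports_dir / f"metrics_{task}.json")
        pooled.to_csv(reports_dir / f"scores_{task}.csv", index=False)
        pooled_by_task[task] = pooled
        summary["stages"][f"evaluate_{task}"] = {
            "auc": report.auc,
            "auc_ci": list(report.auc_ci),
            "accuracy": report.accuracy,
            "precision": report.precision,
            "recall": report.recall,
            "f1": report.f1,
            "n_test_pooled": int(len(pooled)),
        }

    # correlate: subject-level major-depression AI scores vs scales
    if "severity" in pooled_by_task:
        pooled = pooled_by_task["severity"]
        subj_scores = stats.subject_ai_scores(pooled)
        corr = stats.correlation_table(subj_scores, roster)
        corr.to_csv(reports_dir / "correlations.csv", index=False)
        rho_sds = corr.loc[corr["scale"] == "sds", "rho"]
        summary["stages"]["correlate"] = {
            "n_subjects": len(subj_scores),
            "rho_sds": float(rho_sds.iloc[0]) if len(rho_sds) else None,
        }

    # summary.json is written without timing so reruns are byte-identical
    (reports_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    summary["elapsed_s"] = round(time.time() - t0, 1)
    return summary


def _task_classes(manifest: pd.DataFrame, task: str):
    from .evaluation import task_labels

    return task_labels(manifest, task)
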