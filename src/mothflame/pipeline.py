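"""End-to-end pipeline orchestration: augment -> extract (two extractors) ->
select per extractor -> fuse -> evaluate classifier presets.

A single global seed fans out deterministically to every stage via
stage-name-hashed offsets, so a full run is reproducible bit-for-bit from
its config echo, and any stage can be re-run independently with the same
derived seed.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import yaml

from .augmentation import LabeledImage, augment_dataset, load_image_dir
from .evaluation import EvaluationReport, evaluate, format_report_table
from .extraction import BlockStatsExtractor
from .fusion import fuse
from .mfo import MFOConfig
from .selection import FitnessSpec, SelectionResult, select_features
from .synthetic import SyntheticImageSpec, gen_images
from .tables import write_feature_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "derive_seed", "run_pipeline"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC32 of the stage name mixed with the
    global seed, kept below 2**31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Full pipeline parameters; any field can come from a YAML/JSON file."""

    seed: int = 0
    image_dir: Optional[str] = None          # None -> synthetic lesion images
    synthetic_images: dict = field(default_factory=dict)
    augment: bool = True
    augment_repeat: int = 1
    extractor_grids: Sequence[int] = (3, 5)
    select: bool = True
    n_moths: int = 20
    max_iterations: int = 50
    spiral_b: float = 1.0
    alpha: float = 0.99
    inner_classifier: str = "F-KNN"
    cv_folds: int = 5
    classifiers: Sequence[str] = ("F-KNN", "Q-SVM")
    holdout_fraction: float = 0.2
    eval_cv_folds: int = 10
    out_dir: str = "runs/run"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        obj = yaml.safe_load(text)
        return cls(**obj)


def _log(fh, msg: str) -> None:
    stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
    line = f"{stamp} {msg}"
    logger.info(msg)
    fh.write(line + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    The run directory contains the config echo, a plain-text log, per-stage
    feature tables and selection results, and JSON evaluation reports —
    enough metadata to re-run bit-identically.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_echo.yaml").write_text(yaml.safe_dump(asdict(config)))
    log_fh = open(out / "run.log", "w")
    stage = "start"
    try:
        # ---- images -------------------------------------------------------
        stage = "images"
        if config.image_dir is not None:
            images = load_image_dir(config.image_dir)
        else:
            img_spec = SyntheticImageSpec(
                seed=derive_seed(config.seed, "images"),
                **config.synthetic_images,
            )
            images = gen_images(img_spec)
        _log(log_fh, f"images: {len(images)} loaded")

        stage = "augment"
        if config.augment:
            images = augment_dataset(images, repeat=config.augment_repeat)
            _log(log_fh, f"augment: expanded to {len(images)} images")

        # ---- extract / select per extractor ------------------------------
        tables: List[np.ndarray] = []
        labels: Optional[np.ndarray] = None
        selections: Dict[str, SelectionResult] = {}
        for grid in config.extractor_grids:
            stage = f"extract-g{grid}"
            ext = BlockStatsExtractor(grid=grid).fit(images)
            X = ext.transform(images)
            y = ext.labels_of(images)
            labels = y
            write_feature_table(out / f"features_g{grid}.csv", X, y)
            _log(log_fh, f"{stage}: {X.shape[0]} x {X.shape[1]} features")

            if config.select:
                stage = f"select-g{grid}"
                sel_seed = derive_seed(config.seed, stage)
                result = select_features(
                    X, y,
                    MFOConfig(n_moths=config.n_moths,
                              max_iterations=config.max_iterations,
                              spiral_b=config.spiral_b, seed=sel_seed),
                    FitnessSpec(alpha=config.alpha,
                                inner_classifier=config.inner_classifier,
                                cv_folds=config.cv_folds, seed=sel_seed),
                )
                selections[f"g{grid}"] = result
                (out / f"selection_g{grid}.json").write_text(result.to_json())
                X = X[:, result.mask]
                _log(log_fh, f"{stage}: kept {result.n_selected} features, "
                             f"fitness {result.fitness:.4f}")
            tables.append(X)

        # ---- fuse ---------------------------------------------------------
        stage = "fuse"
        if len(tables) != 2:
            raise ValueError("pipeline expects exactly two extractor tables")
        fused = fuse(tables[0], tables[1])
        assert labels is not None
        write_feature_table(out / "features_fused.csv", fused.values, labels)
        (out / "fusion_provenance.json").write_text(fused.provenance_json())
        _log(log_fh, f"fuse: width {fused.values.shape[1]} "
                     f"({fused.d1} + {fused.d2})")

        # ---- evaluate -----------------------------------------------------
        surfaces = {"g%d" % g: t for g, t in zip(config.extractor_grids, tables)}
        surfaces["fused"] = fused.values
        eval_seed = derive_seed(config.seed, "evaluate")
        all_reports: Dict[str, dict] = {}
        for name, X in surfaces.items():
            stage = f"evaluate-{name}"
            reports: List[EvaluationReport] = []
            for preset in config.classifiers:
                rep = evaluate(
                    preset, X, labels,
                    holdout_fraction=config.holdout_fraction,
                    cv_folds=config.eval_cv_folds, seed=eval_seed,
                )
                reports.append(rep)
            all_reports[name] = {r.preset_id: r.as_dict() for r in reports}
            (out / f"report_{name}.txt").write_text(
                format_report_table(reports, "holdout") + "\n"
            )
            best = max(r.holdout.accuracy for r in reports)
            _log(log_fh, f"{stage}: best holdout accuracy {best:.2f}%")
        (out / "reports.json").write_text(json.dumps(all_reports, indent=2))
        _log(log_fh, "pipeline complete")
        return out
    except Exception as exc:
        _log(log_fh, f"FAILED at stage {stage}: {exc}")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        log_fh.close()
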