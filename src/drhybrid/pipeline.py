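"""End-to-end orchestration: preprocess -> basic-model predict -> fuse -> evaluate.

This is desk-scale plumbing: it trains the configured backbones from scratch
on the manifest images (no pretrained weights exist in this environment),
caches their probability outputs, trains/applies the requested fuser and
writes predictions, metrics and a run manifest (seeds, config hash,
versions) into the output directory.
"""
from __future__ import annotations

import hashlib
import json
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .backbones import (BasicModel, TrainConfig, build_basic_model, get_backbone_spec,
                        predict_probabilities, train_basic_model, write_outputs_csv)
from .hybrid import (FusionTrainConfig, HybridSpec, build_hybrid_c, build_hybrid_f,
                     outputs_frame_to_dataset, predict_hybrid_batch, train_hybrid)
from .imageprep import (AugmentConfig, GradedImage, crop_black_border, load_image,
                        read_manifest, resize_for_model)
from .metrics import MetricsReport, evaluate_model, format_report

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    manifest: str
    out_dir: str
    image_dir: str | None = None          # base for relative manifest paths
    backbones: list[str] = field(default_factory=lambda: ["TinyCNN"] * 3)
    loss: str = "ce"
    penalty_mode: str = "hard"
    backbone_epochs: int = 5
    hybrid_kind: str = "a"                # a | f | c
    hybrid_epochs: int = 100
    crop_threshold: int = 10
    positive_grade: int = 0
    seed: int = 0
    augment: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


@_stage("preprocess")
def _preprocess(cfg: PipelineConfig, model_name: str) -> list[GradedImage]:
    df = read_manifest(cfg.manifest)
    base = Path(cfg.image_dir) if cfg.image_dir else Path(cfg.manifest).parent
    images = []
    for row in df.itertuples(index=False):
        img = load_image(base / row.image_path, grade=row.grade)
        cropped = crop_black_border(img, cfg.crop_threshold)
        sized = resize_for_model(cropped.pixels, model_name)
        images.append(GradedImage(pixels=sized, grade=img.grade,
                                  source_id=str(row.image_path)))
    return images


@_stage("train-basic")
def _train_backbones(cfg: PipelineConfig, out_dir: Path) -> dict[str, tuple[BasicModel, list[GradedImage]]]:
    trained: dict[str, tuple[BasicModel, list[GradedImage]]] = {}
    cache: dict[str, list[GradedImage]] = {}
    aug = AugmentConfig(seed=cfg.seed) if cfg.augment else None
    for i, name in enumerate(cfg.backbones):
        spec = get_backbone_spec(name)
        if name not in cache:
            cache[name] = _preprocess(cfg, name)
        instance = f"{name}@{i}"
        model = build_basic_model(spec, seed=cfg.seed + i)
        tcfg = TrainConfig(epochs=cfg.backbone_epochs, loss_name=cfg.loss,
                           penalty_mode=cfg.penalty_mode, seed=cfg.seed + i)
        model, history = train_basic_model(model, cache[name], tcfg, aug)
        pd.DataFrame(history).to_csv(out_dir / f"history_{instance.replace('@','_')}.csv",
                                     index=False)
        trained[instance] = (model, cache[name])
    return trained


@_stage("predict-basic")
def _collect_outputs(trained, out_dir: Path) -> pd.DataFrame:
    records = []
    for instance, (model, images) in trained.items():
        probs = predict_probabilities(model, images)
        for img, p in zip(images, probs):
            rec = {"image_id": img.source_id, "grade": img.grade,
                   "model_name": instance}
            rec.update({f"p{g}": float(p[g]) for g in range(5)})
            records.append(rec)
    frame = pd.DataFrame(records)
    write_outputs_csv(frame, out_dir / "outputs.csv")
    return frame


@_stage("fuse")
def _fuse(cfg: PipelineConfig, outputs: pd.DataFrame, out_dir: Path):
    stacks, grades, order, image_ids = outputs_frame_to_dataset(outputs)
    if cfg.hybrid_kind == "a":
        fused = predict_hybrid_batch("a", stacks)
    else:
        spec = HybridSpec(kind=cfg.hybrid_kind, n_models=len(order))
        build = build_hybrid_f if cfg.hybrid_kind == "f" else build_hybrid_c
        fuser = build(spec, seed=cfg.seed)
        fcfg = FusionTrainConfig(epochs=cfg.hybrid_epochs, seed=cfg.seed)
        fuser, _ = train_hybrid(fuser, stacks, grades, fcfg, model_order=order)
        fused = predict_hybrid_batch(fuser, stacks)
    preds = fused.argmax(axis=1)
    frame = pd.DataFrame({
        "image_id": image_ids,
        "true_grade": grades,
        "pred_grade": preds,
        **{f"p{g}": fused[:, g] for g in range(5)},
    })
    frame.to_csv(out_dir / "predictions.csv", index=False)
    return frame


def run_pipeline(config: PipelineConfig) -> tuple[pd.DataFrame, MetricsReport]:
    """Execute all stages; artifacts land under ``config.out_dir``."""
    if not Path(config.manifest).exists():
        raise FileNotFoundError(f"manifest not found: {config.manifest}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    trained = _train_backbones(config, out_dir)
    outputs = _collect_outputs(trained, out_dir)
    predictions = _fuse(config, outputs, out_dir)

    report, cm = evaluate_model(predictions["true_grade"], predictions["pred_grade"],
                                positive_grade=config.positive_grade)
    (out_dir / "metrics.txt").write_text(format_report(report, cm) + "\n")
    run_manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2) + "\n")
    return predictions, report
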