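"""Pipeline orchestration: configuration, stages and on-disk artifacts.

Stages mirror the screening workflow: generate -> augment -> preprocess
-> extract -> train -> evaluate.  Every stage reads its inputs from and
writes its outputs to files under the run directory, so each stage is
independently runnable and testable; a missing upstream artifact raises
an error naming the file and the stage that produces it.  Every run
writes its fully-resolved configuration next to its outputs, and all
randomness flows from the single config seed.
"""

from __future__ import annotations

import json
import logging
import os
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import evaluation
from .classifier import ArchConfig, MondNet, MondNetModel, TrainConfig
from .features import FeatureConfig, extract_features
from .lbp import LbpParams
from .preprocessing import GabParams, preprocess_batch
from .synthetic import (
    ABNORMAL,
    NORMAL,
    AugmentPolicy,
    LabelledDataset,
    SyntheticSpec,
    augment_dataset,
    generate_dataset,
)

logger = logging.getLogger("mondnet.pipeline")

STAGES = ("generate", "augment", "preprocess", "extract", "train", "evaluate", "all")


class ConfigError(ValueError):
    """Raised for unparseable or out-of-range pipeline configuration."""


class MissingArtifactError(FileNotFoundError):
    """An upstream artifact is absent; the message names the producing stage."""


# ---------------------------------------------------------------------------
# configuration schema (flat, human-editable YAML)


class DataSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_normal: int = Field(78, ge=0)
    n_abnormal: int = Field(52, ge=0)
    height: int = Field(64, ge=32)
    width: int = Field(64, ge=32)
    noise_sd: float = Field(8.0, ge=0)
    lesion_contrast: float = Field(0.5, ge=0.0, le=1.0)


class AugmentSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    factor: int = Field(24, ge=1)
    transforms: list[str] = Field(
        default_factory=lambda: [
            "rotation", "horizontal_flip", "vertical_flip", "brightness", "noise"
        ]
    )


class GabSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sigma_spatial: float = Field(1.0, gt=0)
    sigma_range: float = Field(30.0, gt=0)
    window_radius: int = Field(2, ge=1)


class CifSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    block_size: int = Field(8, ge=1)
    k_min: int = Field(16, ge=1, le=256)
    k_max: int = Field(16, ge=1, le=256)


class LbpSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    neighbors: int = Field(8)
    radius: int = Field(1, ge=1)


class TrainSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    epochs: int = Field(100, ge=1)
    batch_size: int = Field(32, ge=1)
    learning_rate: float = Field(0.02, gt=0)
    val_split: float = Field(0.2, gt=0.0, lt=1.0)
    # feed the preprocessed image tensor alongside the histogram channel
    use_images: bool = False


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    data: DataSettings = Field(default_factory=DataSettings)
    augment: AugmentSettings = Field(default_factory=AugmentSettings)
    gab: GabSettings = Field(default_factory=GabSettings)
    cif: CifSettings = Field(default_factory=CifSettings)
    lbp: LbpSettings = Field(default_factory=LbpSettings)
    train: TrainSettings = Field(default_factory=TrainSettings)

    # ---- typed views consumed by the library modules --------------------

    def synthetic_spec(self) -> SyntheticSpec:
        d = self.data
        return SyntheticSpec(
            n_normal=d.n_normal,
            n_abnormal=d.n_abnormal,
            height=d.height,
            width=d.width,
            seed=self.seed,
            noise_sd=d.noise_sd,
            lesion_contrast=d.lesion_contrast,
        )

    def augment_policy(self) -> AugmentPolicy:
        return AugmentPolicy(
            factor=self.augment.factor,
            transforms=frozenset(self.augment.transforms),
            seed=self.seed + 1,
        )

    def gab_params(self) -> GabParams:
        g = self.gab
        return GabParams(
            sigma_spatial=g.sigma_spatial,
            sigma_range=g.sigma_range,
            window_radius=g.window_radius,
        )

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(
            block_size=self.cif.block_size,
            k_min=self.cif.k_min,
            k_max=self.cif.k_max,
            lbp=LbpParams(neighbors=self.lbp.neighbors, radius=self.lbp.radius),
        )

    def train_config(self) -> TrainConfig:
        t = self.train
        return TrainConfig(
            epochs=t.epochs,
            batch_size=t.batch_size,
            learning_rate=t.learning_rate,
            val_split=t.val_split,
            seed=self.seed + 2,
        )


def validate_config(text: str | None) -> PipelineConfig:
    """Parse and range-check YAML config text; empty input means all defaults."""
    raw = yaml.safe_load(text) if text else None
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
        raise ConfigError("invalid config: " + "; ".join(lines)) from exc


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    return validate_config(Path(path).read_text())


def dump_config(config: PipelineConfig) -> str:
    return yaml.safe_dump(config.model_dump(), sort_keys=False)


# ---------------------------------------------------------------------------
# artifacts


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {path}; run the '{producing_stage}' stage first"
        )
    return path


def _stratified_split(
    labels: np.ndarray, val_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified train/validation index split."""
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(len(idx) * val_fraction)))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.array(train_idx)), np.sort(np.array(val_idx))


# ---------------------------------------------------------------------------
# stages


def _log(stage: str, seed: int, t0: float, **counts) -> None:
    kv = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s seed=%d elapsed=%.2fs %s", stage, seed, time.monotonic() - t0, kv)


def run_stage(stage: str, config: PipelineConfig, out_dir: str | Path) -> None:
    """Run one pipeline stage (or ``all``) with artifacts under ``out_dir``."""
    if stage not in STAGES:
        raise ConfigError(f"unknown stage '{stage}'; choose from {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _atomic_write(out / "config.yaml", dump_config(config))
    if stage == "all":
        for s in ("generate", "augment", "preprocess", "extract", "train", "evaluate"):
            run_stage(s, config, out)
        return
    t0 = time.monotonic()

    if stage == "generate":
        data = generate_dataset(config.synthetic_spec())
        data.save(out / "raw", seed=config.seed)
        _log(stage, config.seed, t0, images=len(data), normal=data.count(NORMAL),
             abnormal=data.count(ABNORMAL))

    elif stage == "augment":
        _require(out / "raw" / "manifest.csv", "generate")
        data = LabelledDataset.load(out / "raw")
        combined = augment_dataset(data, config.augment_policy())
        combined.save(out / "augmented", seed=config.seed)
        _log(stage, config.seed, t0, originals=len(data), combined=len(combined))

    elif stage == "preprocess":
        src = out / "augmented"
        if not (src / "manifest.csv").exists():
            src = out / "raw"
        _require(src / "manifest.csv", "generate")
        data = LabelledDataset.load(src)
        filtered = preprocess_batch(data, config.gab_params())
        filtered.save(out / "preprocessed", seed=config.seed)
        _log(stage, config.seed, t0, images=len(filtered))

    elif stage == "extract":
        _require(out / "preprocessed" / "manifest.csv", "preprocess")
        data = LabelledDataset.load(out / "preprocessed")
        frame = extract_features(data, config.feature_config())
        frame.to_csv(out / "features.csv", index=False)
        _log(stage, config.seed, t0, rows=len(frame), cols=frame.shape[1])

    elif stage == "train":
        _require(out / "features.csv", "extract")
        frame = pd.read_csv(out / "features.csv")
        tc = config.train_config()
        labels = frame["label"].to_numpy()
        train_idx, val_idx = _stratified_split(labels, tc.val_split, tc.seed)
        train_images = None
        if config.train.use_images:
            _require(out / "preprocessed" / "manifest.csv", "preprocess")
            data = LabelledDataset.load(out / "preprocessed")
            train_images = [data.images[i] for i in train_idx]
        model = MondNet.from_dataframe(frame.iloc[train_idx], images=train_images)
        results = model.fit(tc)
        results.save(out / "model.npz", out / "history.csv")
        _atomic_write(
            out / "split.json",
            json.dumps({"train": train_idx.tolist(), "val": val_idx.tolist()}),
        )
        _log(stage, config.seed, t0, train=len(train_idx), val=len(val_idx),
             final_loss=f"{results.final_loss:.4f}")

    elif stage == "evaluate":
        _require(out / "model.npz", "train")
        _require(out / "split.json", "train")
        _require(out / "features.csv", "extract")
        frame = pd.read_csv(out / "features.csv")
        split = json.loads((out / "split.json").read_text())
        val = frame.iloc[split["val"]]
        model = MondNetModel.load(out / "model.npz")
        feature_cols = [c for c in frame.columns if c not in ("path", "label", "provenance")]
        val_images = None
        if model.image_shape is not None:
            data = LabelledDataset.load(out / "preprocessed")
            val_images = [data.images[i] for i in split["val"]]
        preds, _proba = model.predict(val[feature_cols].to_numpy(float), val_images)
        counts = evaluation.tally(list(preds), val["label"].tolist())
        report = evaluation.compute_metrics(counts)
        evaluation.write_metrics(report, counts, out / "metrics.json")
        evaluation.per_class_report(list(preds), val["label"].tolist()).to_csv(
            out / "metrics_by_class.csv", index=False
        )
        _log(stage, config.seed, t0, val=len(val), accuracy=f"{report.accuracy:.2f}")
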