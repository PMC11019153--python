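"""Configuration schema and the end-to-end pipeline.

``run_pipeline`` chains every stage on simulated data: generate labeled
detail images for the training conditions and for the treated groups,
segment and featurize them, train the QC forest with threshold calibration
and discard images it rejects, embed the kept nuclei, train the
proliferating-vs-senescent SVM on kept training-condition nuclei, classify
the kept treated nuclei, and write feature tables, summaries and a run
manifest.  Identical config + seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
import tempfile
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__ as _version
from .datasets import detail_features
from .models import (
    QCParams,
    apply_qc,
    classify_treated,
    condition_summaries,
    embed,
    train_condition,
    train_qc,
)
from .synthesis import (
    CONDITION_DEFAULTS,
    ConditionParams,
    generate_population,
    substream_seed,
)
from .segmentation import StedSegParams
from .texture import GLCMParams, PROFILES

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "validate_config",
    "load_config",
    "run_pipeline",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ConditionParamsConfig(_Strict):
    area_mean_px: float
    area_sd_px: float
    texture_corr_len_px: float
    foci_density: float
    foci_contrast: float
    background_level: float = 0.05
    noise_sd: float = 0.02
    intensity_scale: float = 1.0

    def build(self) -> ConditionParams:
        return ConditionParams(**self.model_dump())


class SynthesisConfig(_Strict):
    n_cells_per_condition: int = Field(100, ge=1)
    train_conditions: tuple[str, ...] = ("proliferating", "senescent")
    treated_conditions: tuple[str, ...] = ("treated_d3", "treated_d6")
    n_treated_per_condition: int = Field(50, ge=0)
    bad_fraction: float = Field(0.2, ge=0.0, lt=1.0)
    detail_shape: tuple[int, int] = (256, 256)
    pixel_size_nm: float = Field(25.0, gt=0)
    condition_params: dict[str, ConditionParamsConfig] = {}

    def params_map(self) -> dict[str, ConditionParams]:
        out = dict(CONDITION_DEFAULTS)
        out.update({k: v.build() for k, v in self.condition_params.items()})
        return out


class DetectionConfig(_Strict):
    k_clusters: int = Field(2, ge=2)
    gaussian_sigma_px: float = Field(2.0, gt=0)
    erosion_radius_px: int = Field(3, ge=0)


class StedSegConfig(_Strict):
    q_low: float = 0.025
    q_high: float = 0.995
    blur_sigma_px: float = Field(16.0, gt=0)
    min_object_px: int = Field(512, ge=0)
    max_hole_px: int = Field(512, ge=0)
    remove_objects_first: bool = True
    min_blur_range: float = Field(0.15, ge=0)

    @model_validator(mode="after")
    def _check_quantiles(self):
        if not (0.0 <= self.q_low < self.q_high <= 1.0):
            raise ValueError("sted_seg: need 0 <= q_low < q_high <= 1")
        return self

    def build(self) -> StedSegParams:
        return StedSegParams(**self.model_dump())


class GLCMConfig(_Strict):
    distances: Optional[tuple[int, ...]] = None  # None -> profile default
    angles_deg: tuple[float, ...] = (0.0, 90.0)
    levels: int = Field(64, ge=2)
    symmetric: bool = True
    normed: bool = True
    pre_blur_sigma_px: float = Field(0.5, ge=0)

    @model_validator(mode="after")
    def _check_distances(self):
        if self.distances is not None and any(d < 1 for d in self.distances):
            raise ValueError("glcm: distances must be positive")
        return self

    def build(self, profile: str) -> GLCMParams:
        dist = self.distances or tuple(PROFILES[profile]["distances"])
        return GLCMParams(
            distances=tuple(dist),
            angles=tuple(math.radians(a) for a in self.angles_deg),
            levels=self.levels, symmetric=self.symmetric, normed=self.normed,
            pre_blur_sigma_px=self.pre_blur_sigma_px,
        )


class QCConfig(_Strict):
    n_trees: int = Field(500, ge=1)
    n_folds: int = Field(5, ge=2)
    target_precision: float = Field(0.95, gt=0, le=1)
    qc_threshold_override: Optional[float] = None

    def build(self, seed: int) -> QCParams:
        return QCParams(
            n_trees=self.n_trees, n_folds=self.n_folds,
            target_precision=self.target_precision, seed=seed,
        )


class SVMConfig(_Strict):
    kernel: str = "rbf"
    C: float = Field(1.0, gt=0)


class EmbeddingConfig(_Strict):
    enabled: bool = True
    perplexity: float = Field(30.0, gt=0)


class PipelineConfig(_Strict):
    profile: Literal["sted", "confocal"] = "sted"
    master_seed: int = 11
    synthesis: SynthesisConfig = SynthesisConfig()
    detection: DetectionConfig = DetectionConfig()
    sted_seg: StedSegConfig = StedSegConfig()
    glcm: GLCMConfig = GLCMConfig()
    qc: QCConfig = QCConfig()
    svm: SVMConfig = SVMConfig()
    embedding: EmbeddingConfig = EmbeddingConfig()

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(raw: dict | None) -> PipelineConfig:
    """Validate a raw config document; unknown keys are rejected and
    defaults reproduce the published constants (distances, quantiles,
    sigma values, 512-px filters, erosion radius 3, 5 folds, 0.95 target)."""
    return PipelineConfig.model_validate(raw or {})


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


class RunManifest(dict):
    """Plain-dict manifest with atomic JSON persistence."""

    def write(self, path) -> None:
        path = Path(path)
        fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
        try:
            with os.fdopen(fd, "w") as fh:
                json.dump(self, fh, indent=2, sort_keys=True)
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute the full simulated workflow; returns the written manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.master_seed
    syn = config.synthesis
    params_map = syn.params_map()
    glcm_params = config.glcm.build(config.profile)
    seg_params = config.sted_seg.build()

    with _stage("synthesis"):
        images, truths = generate_population(
            syn.n_cells_per_condition, syn.train_conditions,
            seed=substream_seed(seed, "train-pop"),
            bad_fraction=syn.bad_fraction, shape=syn.detail_shape,
            pixel_size_nm=syn.pixel_size_nm, condition_params=params_map,
        )
        treated: dict[str, tuple] = {}
        if syn.n_treated_per_condition > 0:
            for gi, group in enumerate(syn.treated_conditions):
                treated[group] = generate_population(
                    syn.n_treated_per_condition, (group,),
                    seed=substream_seed(seed, "treated-pop", gi),
                    bad_fraction=syn.bad_fraction, shape=syn.detail_shape,
                    pixel_size_nm=syn.pixel_size_nm, condition_params=params_map,
                )

    with _stage("features"):
        frames = [
            detail_features(
                images, truths, profile=config.profile,
                seg_params=seg_params, glcm_params=glcm_params,
            )
        ]
        frames[0]["meta_group"] = "training"
        for group, (imgs_g, truths_g) in treated.items():
            df_g = detail_features(
                imgs_g, truths_g, profile=config.profile,
                seg_params=seg_params, glcm_params=glcm_params,
            )
            df_g["meta_group"] = group
            frames.append(df_g)
        features = pd.concat(frames, ignore_index=True)
        features.to_csv(out / "features.csv", index=False)

    with _stage("qc"):
        train_mask = features["meta_group"] == "training"
        labels_good = features.loc[train_mask, "meta_qc_label"] == "good"
        if labels_good.nunique() < 2:
            # nothing to learn from a single-class manual sort: pass-through
            threshold = config.qc.qc_threshold_override or 0.0
            proba = np.ones(len(features))
            keep = proba >= threshold
            qc_threshold = float(threshold)
        else:
            qc_model = train_qc(
                features.loc[train_mask],
                labels_good,
                config.qc.build(seed=substream_seed(seed, "qc")),
            )
            threshold = (
                config.qc.qc_threshold_override
                if config.qc.qc_threshold_override is not None
                else qc_model.threshold
            )
            qc_model = dataclasses.replace(qc_model, threshold=threshold)
            keep, proba = apply_qc(qc_model, features)
            qc_threshold = float(qc_model.threshold)
        qc_table = pd.DataFrame(
            {
                "cell_id": features["meta_cell_id"],
                "group": features["meta_group"],
                "qc_probability_good": proba,
                "kept": keep,
            }
        )
        qc_table.to_csv(out / "qc.csv", index=False)
        kept = features.loc[keep].reset_index(drop=True)

    with _stage("embedding"):
        emb_n = 0
        if config.embedding.enabled and len(kept) > 3 * config.embedding.perplexity:
            emb = embed(
                kept, perplexity=config.embedding.perplexity,
                seed=substream_seed(seed, "embed"),
            )
            pd.DataFrame(
                {
                    "cell_id": kept["meta_cell_id"],
                    "group": kept["meta_group"],
                    "condition": kept["meta_condition"],
                    "tsne_1": emb.coords[:, 0],
                    "tsne_2": emb.coords[:, 1],
                }
            ).to_csv(out / "embedding.csv", index=False)
            emb_n = len(kept)

    with _stage("classification"):
        kept_train = kept[kept["meta_group"] == "training"]
        cls_train = kept_train[
            kept_train["meta_condition"].isin(["proliferating", "senescent"])
        ]
        cond_model = train_condition(
            cls_train, cls_train["meta_condition"],
            kernel=config.svm.kernel, C=config.svm.C,
        )
        treated_kept = {
            g: kept[kept["meta_group"] == g]
            for g in syn.treated_conditions
            if (kept["meta_group"] == g).any()
        }
        confusion = classify_treated(cond_model, treated_kept)
        confusion.to_frame().to_csv(out / "confusion.csv", index=False)

    with _stage("report"):
        good_kept = kept[kept["meta_qc_label"] == "good"]
        condition_summaries(
            good_kept, good_kept["meta_condition"]
        ).to_csv(out / "condition_summaries.csv", index=False)

    n_classified = int(sum(len(df) for df in treated_kept.values()))
    manifest = RunManifest(
        config_hash=config.config_hash(),
        master_seed=seed,
        package_version=_version,
        counts={
            "generated_total": int(len(features)),
            "generated_good": int((features["meta_qc_label"] == "good").sum()),
            "generated_bad": int((features["meta_qc_label"] == "bad").sum()),
            "kept_by_qc": int(keep.sum()),
            "embedded": emb_n,
            "classified_treated": n_classified,
        },
        qc_threshold=qc_threshold,
        confusion={
            g: fr for g, fr in confusion.fractions.items()
        },
    )
    manifest.write(out / "manifest.json")
    return manifest
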