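"""Convenience assemblies: simulate detail images and turn them into feature tables.

These helpers wire synthesis -> segmentation -> texture for the common
benchmark layouts (labeled QC sets, per-condition populations) so tests,
examples and the acceptance checks all run the same code path.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .segmentation import StedSegParams, segment_sted_foreground
from .synthesis import (
    BAD_MODES,
    CONDITION_DEFAULTS,
    ConditionParams,
    Image2D,
    SceneTruth,
    generate_bad_detail,
    generate_nucleus_detail,
    substream_seed,
)
from .texture import GLCMParams, extract_features, features_to_frame

__all__ = ["detail_features", "make_qc_dataset", "make_condition_dataset"]


def detail_features(
    images: Sequence[Image2D],
    truths: Sequence[SceneTruth] | None = None,
    profile: str = "sted",
    seg_params: StedSegParams | None = None,
    glcm_params: GLCMParams | None = None,
) -> pd.DataFrame:
    """Segment each detail image and extract its feature vector.

    When ground truths are supplied their condition / QC labels are carried
    along as ``meta_condition`` / ``meta_qc_label`` columns.
    """
    records = []
    for idx, img in enumerate(images):
        seg = segment_sted_foreground(img, seg_params)
        prov = {"cell_id": idx}
        if truths is not None:
            t = truths[idx]
            prov.update(
                condition=t.condition, qc_label=t.qc_label,
                bad_mode=t.bad_mode or "", seed=t.rng_seed,
            )
        rec = extract_features(
            img, seg.mask, profile=profile, params=glcm_params, provenance=prov
        )
        records.append(rec)
    return features_to_frame(records)


def make_qc_dataset(
    n_good: int,
    n_bad: int,
    seed: int,
    shape: tuple[int, int] = (256, 256),
    conditions: Sequence[str] = ("proliferating", "senescent"),
    condition_params: dict[str, ConditionParams] | None = None,
    profile: str = "sted",
):
    """A labeled good/bad detail-image set with extracted features.

    Good images alternate between the given conditions; bad images cycle
    through the five failure modes and the condition parameter sets.
    Returns ``(features_frame, good_labels, truths)``.
    """
    cp = dict(CONDITION_DEFAULTS)
    if condition_params:
        cp.update(condition_params)
    images, truths = [], []
    for j in range(n_good):
        cond = conditions[j % len(conditions)]
        img, truth = generate_nucleus_detail(
            cp[cond], shape=shape, seed=substream_seed(seed, "qc-good", j),
            condition=cond,
        )
        images.append(img)
        truths.append(truth)
    for j in range(n_bad):
        mode = BAD_MODES[j % len(BAD_MODES)]
        cond = conditions[j % len(conditions)]
        img, truth = generate_bad_detail(
            mode, seed=substream_seed(seed, "qc-bad", j), params=cp[cond],
            shape=shape, condition=cond,
        )
        images.append(img)
        truths.append(truth)
    df = detail_features(images, truths, profile=profile)
    labels = [t.qc_label == "good" for t in truths]
    return df, labels, truths


def make_condition_dataset(
    n_per_condition: int,
    conditions: Sequence[str],
    seed: int,
    shape: tuple[int, int] = (256, 256),
    condition_params: dict[str, ConditionParams] | None = None,
    profile: str = "sted",
):
    """Good-only per-condition feature table; returns ``(frame, labels)``."""
    cp = dict(CONDITION_DEFAULTS)
    if condition_params:
        cp.update(condition_params)
    images, truths = [], []
    for ci, cond in enumerate(conditions):
        for j in range(n_per_condition):
            img, truth = generate_nucleus_detail(
                cp[cond], shape=shape,
                seed=substream_seed(seed, "cond", ci, j), condition=cond,
            )
            images.append(img)
            truths.append(truth)
    df = detail_features(images, truths, profile=profile)
    return df, [t.condition for t in truths]
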