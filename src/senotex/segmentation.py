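"""Stitching, nucleus detection and foreground segmentation.

Overview tiles are max-projected and placed on a common canvas at integer
offsets derived from their stage coordinates; overlapping pixels are fused
by per-pixel averaging.  Candidate nuclei are found by unsupervised
clustering of per-pixel features (raw intensity, Gaussian-smoothed
intensity, Sobel gradient magnitude) with k-means, taking the cluster of
highest mean raw intensity as foreground, eroding with a radius-3 disk to
drop small spurious detections, and labelling 8-connected components.

Single-nucleus detail images are segmented with the minimum-cross-entropy
(Li) threshold applied to a strongly blurred (sigma = 16 px) version of the
quantile-normalized image, followed by removal of objects smaller than
512 px and filling of holes smaller than 512 px.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import sobel, threshold_li
from skimage.measure import label as cc_label
from skimage.morphology import (
    disk,
    erosion,
    remove_small_holes,
    remove_small_objects,
)
from sklearn.cluster import KMeans

from .synthesis import Image2D, ImageStack, TileSet

__all__ = [
    "LabelMask",
    "DetectionParams",
    "StedSegParams",
    "SegmentationResult",
    "max_project",
    "stitch_tiles",
    "detect_nuclei_overview",
    "segment_sted_foreground",
    "label_bbox",
    "crop_detail",
    "detection_table",
]


@dataclass
class LabelMask:
    """Integer-labelled nucleus instances (0 = background)."""

    labels: np.ndarray
    n_objects: int

    def __post_init__(self) -> None:
        uniq = np.unique(self.labels)
        n = int((uniq > 0).sum())
        if n != self.n_objects:
            raise ValueError("n_objects inconsistent with label raster")


@dataclass(frozen=True)
class DetectionParams:
    """k-means pixel-clustering detector settings."""

    k_clusters: int = 2
    gaussian_sigma_px: float = 2.0
    erosion_radius_px: int = 3
    seed: int = 0
    n_init: int = 10
    #: foreground is accepted only when its raw-intensity cluster mean sits
    #: this many pooled within-cluster sds above the next cluster; splitting
    #: unimodal noise yields ~2.7, real nuclei >> 4
    min_cluster_separation: float = 4.0
    #: erosion can pinch tiny crumbs off object rims; drop anything smaller
    min_object_px: int = 64

    def __post_init__(self) -> None:
        if self.k_clusters < 2:
            raise ValueError("k_clusters must be >= 2")
        if self.erosion_radius_px < 0:
            raise ValueError("erosion_radius_px must be >= 0")


@dataclass(frozen=True)
class StedSegParams:
    """Detail-image foreground segmentation settings."""

    q_low: float = 0.025
    q_high: float = 0.995
    blur_sigma_px: float = 16.0
    min_object_px: int = 512
    max_hole_px: int = 512
    remove_objects_first: bool = True
    #: blurred images whose dynamic range falls below this are treated as
    #: signal-free (guards Li thresholding against stretched pure noise)
    min_blur_range: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_low < self.q_high <= 1.0):
            raise ValueError("need 0 <= q_low < q_high <= 1")


@dataclass
class SegmentationResult:
    mask: np.ndarray
    norm_img: Image2D
    degenerate: bool = False


def max_project(stack: ImageStack) -> Image2D:
    """Per-pixel maximum across planes."""
    out = np.maximum.reduce([p.pixels for p in stack.planes])
    return Image2D(out, pixel_size_nm=stack.planes[0].pixel_size_nm)


def stitch_tiles(tiles: TileSet) -> Image2D:
    """Fuse max-projected tiles at their stage coordinates.

    Tiles are placed at the integer pixel offset nearest their stage
    coordinate; overlapping pixels are averaged.  The output covers the
    bounding box of all tile footprints.
    """
    psz = tiles.pixel_size_nm
    for st in tiles.tiles:
        if any(abs(p.pixel_size_nm - psz) > 1e-9 for p in st.planes):
            raise ValueError("all tiles must share one pixel size")
    projs = [max_project(st).pixels for st in tiles.tiles]
    offs = [
        (int(round(y / psz)), int(round(x / psz))) for (x, y) in tiles.stage_coords
    ]
    r_min = min(o[0] for o in offs)
    c_min = min(o[1] for o in offs)
    r_max = max(o[0] + p.shape[0] for o, p in zip(offs, projs))
    c_max = max(o[1] + p.shape[1] for o, p in zip(offs, projs))
    acc = np.zeros((r_max - r_min, c_max - c_min))
    wgt = np.zeros_like(acc)
    for (r0, c0), p in zip(offs, projs):
        r0, c0 = r0 - r_min, c0 - c_min
        acc[r0 : r0 + p.shape[0], c0 : c0 + p.shape[1]] += p
        wgt[r0 : r0 + p.shape[0], c0 : c0 + p.shape[1]] += 1.0
    out = np.divide(acc, wgt, out=np.zeros_like(acc), where=wgt > 0)
    return Image2D(out, pixel_size_nm=psz)


def cluster_foreground(img: Image2D, p: DetectionParams) -> np.ndarray:
    """Raw k-means foreground mask (before erosion); exposed for testing."""
    pix = img.pixels
    if np.ptp(pix) == 0:
        return np.zeros(pix.shape, dtype=bool)
    feats = np.stack(
        [
            pix,
            ndimage.gaussian_filter(pix, p.gaussian_sigma_px),
            sobel(pix),
        ],
        axis=-1,
    ).reshape(-1, 3)
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    km = KMeans(
        n_clusters=p.k_clusters, n_init=p.n_init, random_state=p.seed
    ).fit((feats - mu) / sd)
    flat = pix.reshape(-1)
    raw_means = np.array(
        [
            flat[km.labels_ == k].mean() if (km.labels_ == k).any() else -np.inf
            for k in range(p.k_clusters)
        ]
    )
    order = np.argsort(raw_means)
    fg_cluster = int(order[-1])
    # guard: a k-means split of pure noise produces clusters whose mean gap
    # is only ~2.7 pooled sds; demand a clearly bimodal separation
    within = np.sqrt(
        np.mean((flat - raw_means[km.labels_]) ** 2)
    )
    gap = raw_means[order[-1]] - raw_means[order[-2]]
    if within > 0 and gap < p.min_cluster_separation * within:
        return np.zeros(pix.shape, dtype=bool)
    return (km.labels_ == fg_cluster).reshape(pix.shape)


def detect_nuclei_overview(img: Image2D, p: DetectionParams | None = None) -> LabelMask:
    """Detect nuclei in a (stitched, max-projected) overview image."""
    p = p or DetectionParams()
    fg = cluster_foreground(img, p)
    if p.erosion_radius_px > 0:
        fg = erosion(fg, disk(p.erosion_radius_px))
    if p.min_object_px > 1:
        fg = remove_small_objects(fg, max_size=p.min_object_px - 1, connectivity=2)
    labels = cc_label(fg, connectivity=2)
    # relabel densely in case removal left gaps
    labels = cc_label(labels > 0, connectivity=2)
    return LabelMask(labels=labels, n_objects=int(labels.max()))


def segment_sted_foreground(
    img: Image2D, p: StedSegParams | None = None
) -> SegmentationResult:
    """Quantile-normalize and segment one detail image.

    Degenerate inputs (constant image, or no structure surviving the strong
    blur) yield an all-zero normalized image / empty mask with the
    ``degenerate`` flag set.
    """
    p = p or StedSegParams()
    raw = img.pixels
    if min(raw.shape) < 128:
        raise ValueError("detail segmentation expects frames >= 128 px")
    ql, qh = np.quantile(raw, [p.q_low, p.q_high])
    if qh <= ql:
        zeros = np.zeros_like(raw)
        return SegmentationResult(
            mask=np.zeros(raw.shape, dtype=bool),
            norm_img=Image2D(zeros, pixel_size_nm=img.pixel_size_nm),
            degenerate=True,
        )
    norm = np.clip((raw - ql) / (qh - ql), 0.0, 1.0)
    norm_img = Image2D(norm, pixel_size_nm=img.pixel_size_nm)
    blurred = ndimage.gaussian_filter(norm, p.blur_sigma_px)
    if np.ptp(blurred) < p.min_blur_range:
        return SegmentationResult(
            mask=np.zeros(raw.shape, dtype=bool), norm_img=norm_img, degenerate=True
        )
    mask = blurred > threshold_li(blurred)
    # "< 512 px" is strict: the library's max_size removes areas <= max_size
    ops = [
        lambda m: remove_small_objects(m, max_size=p.min_object_px - 1, connectivity=2),
        lambda m: remove_small_holes(m, max_size=p.max_hole_px - 1, connectivity=2),
    ]
    if not p.remove_objects_first:
        ops.reverse()
    for op in ops:
        mask = op(mask)
    return SegmentationResult(mask=mask, norm_img=norm_img, degenerate=False)


def label_bbox(
    mask: LabelMask, lab: int, pad_px: int, shape: tuple[int, int]
) -> tuple[slice, slice]:
    """Padded, frame-clipped bounding box (half-open slices) of one label."""
    where = mask.labels == lab
    if not where.any():
        raise ValueError(f"label {lab} not present")
    rows = np.any(where, axis=1).nonzero()[0]
    cols = np.any(where, axis=0).nonzero()[0]
    r0 = max(0, rows[0] - pad_px)
    r1 = min(shape[0], rows[-1] + 1 + pad_px)
    c0 = max(0, cols[0] - pad_px)
    c1 = min(shape[1], cols[-1] + 1 + pad_px)
    return slice(r0, r1), slice(c0, c1)


def crop_detail(
    scene: Image2D, lab: int, mask: LabelMask, pad_px: int = 0
) -> Image2D:
    """Axis-aligned crop of one detected nucleus from the scene."""
    rs, cs = label_bbox(mask, lab, pad_px, scene.shape)
    return Image2D(scene.pixels[rs, cs].copy(), pixel_size_nm=scene.pixel_size_nm)


def detection_table(mask: LabelMask, scene_id: str = "scene"):
    """Per-detection centroid/area table (one row per label)."""
    rows = []
    for lab in range(1, mask.n_objects + 1):
        where = mask.labels == lab
        rr, cc = np.nonzero(where)
        rows.append(
            {
                "scene_id": scene_id,
                "label": lab,
                "centroid_row": float(rr.mean()),
                "centroid_col": float(cc.mean()),
                "area_px": int(where.sum()),
            }
        )
    return pd.DataFrame(
        rows, columns=["scene_id", "label", "centroid_row", "centroid_col", "area_px"]
    )
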