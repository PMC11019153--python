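"""Synthetic fluorescence-microscopy scenes of DNA-stained nuclei.

This module generates the three kinds of images the analysis pipeline
consumes, with known ground truth:

* single-nucleus *detail* images (the super-resolution mid-plane view of one
  nucleus), whose chromatin texture, size and intensity depend on a
  biological condition (proliferating, replicatively senescent, or
  drug-treated for N days);
* *bad* detail images reproducing the failure modes of unattended automated
  acquisition (out-of-focus shots, nuclei clipped at the frame edge, blank
  scanner rows, empty frames, two-nucleus doublets);
* tiled *overview* z-stacks covering a large field of view with overlapping
  tiles acquired in a spiral, for the stitching/detection stages.

The chromatin texture model is deliberately simple: the nuclear interior is
a band-limited Gaussian random field (white noise smoothed with a Gaussian
of width ``texture_corr_len_px``) riding on a uniform baseline, plus
hard-disk heterochromatin-like foci.  GLCM statistics respond smoothly and
monotonically to the field's correlation length and the foci contrast,
which is the property the downstream texture features need; no attempt is
made at photorealism.

Every generator is a pure function of its parameters and an integer seed.
Sub-streams are derived with :func:`stream` (a counter-based split of a
``numpy`` ``SeedSequence``) so independent pieces of a scene are
independently reproducible.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "Image2D",
    "ImageStack",
    "TileSet",
    "ConditionParams",
    "SceneTruth",
    "CONDITION_DEFAULTS",
    "BAD_MODES",
    "NucleusSizingError",
    "PlacementError",
    "stream",
    "generate_nucleus_detail",
    "generate_bad_detail",
    "generate_overview_scene",
    "generate_population",
    "spiral_order",
]

#: sd of the chromatin random field relative to the unit interior baseline
TEXTURE_AMPLITUDE = 0.25
#: radius (px) of heterochromatin-like foci disks
FOCUS_RADIUS_PX = 3
#: clearance (px) demanded between a nucleus and the frame border
FIT_MARGIN_PX = 8
#: Gaussian sigma (px) applied to the off-focus planes of overview stacks
DEFOCUS_SIGMA_PX = 4.0
#: attenuation of off-focus planes relative to the sharp mid-plane
DEFOCUS_ATTENUATION = 0.5

BAD_MODES = ("out_of_focus", "truncated", "blank_rows", "empty", "doublet")


class NucleusSizingError(ValueError):
    """Raised when a sampled nucleus cannot fit into the requested frame."""


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap."""


def stream(seed: int, *key) -> np.random.Generator:
    """Return an independent, reproducible random stream.

    Sub-streams are identified by a key of integers and/or strings; strings
    are hashed with CRC-32.  The same ``(seed, key)`` always yields the same
    stream, and distinct keys yield statistically independent streams.
    """
    ints = tuple(
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in key
    )
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=ints))


def substream_seed(seed: int, *key) -> int:
    """Derive a child integer seed (< 2**31) from a master seed and a key."""
    ints = tuple(
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in key
    )
    state = np.random.SeedSequence(entropy=int(seed), spawn_key=ints).generate_state(1)
    return int(state[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# carriers
# ---------------------------------------------------------------------------


@dataclass
class Image2D:
    """A single grayscale raster with physical pixel size metadata."""

    pixels: np.ndarray
    pixel_size_nm: float = 25.0
    bit_depth_hint: int = 16

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim != 2 or p.shape[0] < 1 or p.shape[1] < 1:
            raise ValueError("Image2D requires a non-empty 2D raster")
        if not np.all(np.isfinite(p)):
            raise ValueError("Image2D pixels must be finite")
        if (p < 0).any():
            raise ValueError("Image2D pixels must be non-negative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        self.pixels = p

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class ImageStack:
    """An ordered z-stack of equally shaped planes."""

    planes: list[Image2D]
    z_step_nm: float = 300.0

    def __post_init__(self) -> None:
        if len(self.planes) < 1:
            raise ValueError("ImageStack requires at least one plane")
        shp = self.planes[0].shape
        if any(p.shape != shp for p in self.planes):
            raise ValueError("all planes must share a shape")
        if self.z_step_nm <= 0:
            raise ValueError("z_step_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes[0].shape


@dataclass
class TileSet:
    """Overview tiles plus the stage coordinates they were acquired at.

    ``stage_coords`` holds one ``(x_nm, y_nm)`` pair per tile; x maps to
    columns and y to rows of the common scene frame.
    """

    tiles: list[ImageStack]
    stage_coords: list[tuple[float, float]]
    overlap_fraction: float = 0.2
    pixel_size_nm: float = 100.0

    def __post_init__(self) -> None:
        if len(self.tiles) != len(self.stage_coords):
            raise ValueError("one stage coordinate per tile required")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class ConditionParams:
    """Generator knobs for one biological condition.

    Areas are in px² at the detail pixel size; ``texture_corr_len_px`` is
    the Gaussian smoothing width of the chromatin field (larger = smoother,
    more homogeneous chromatin); ``foci_density`` is per µm².
    """

    area_mean_px: float
    area_sd_px: float
    texture_corr_len_px: float
    foci_density: float
    foci_contrast: float
    background_level: float = 0.05
    noise_sd: float = 0.02
    intensity_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.area_mean_px <= 0 or self.area_sd_px <= 0:
            raise ValueError("areas must be positive")
        if self.texture_corr_len_px <= 0:
            raise ValueError("texture_corr_len_px must be positive")
        for name in ("foci_density", "foci_contrast", "background_level", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.intensity_scale <= 0:
            raise ValueError("intensity_scale must be positive")


# Condition defaults encode the ordinal phenotype: senescent nuclei are
# ~1.7x larger with smoother (longer-correlated), lower-contrast chromatin
# and fewer bright foci; 3-day treatment sits midway; 6/9-day treatment is
# senescent-like.
CONDITION_DEFAULTS: dict[str, ConditionParams] = {
    "proliferating": ConditionParams(
        area_mean_px=7000.0, area_sd_px=800.0, texture_corr_len_px=1.5,
        foci_density=4.0, foci_contrast=0.35,
    ),
    "senescent": ConditionParams(
        area_mean_px=12000.0, area_sd_px=1100.0, texture_corr_len_px=3.0,
        foci_density=1.5, foci_contrast=0.15,
    ),
    "treated_d3": ConditionParams(
        area_mean_px=9500.0, area_sd_px=950.0, texture_corr_len_px=2.25,
        foci_density=2.75, foci_contrast=0.25,
    ),
    "treated_d6": ConditionParams(
        area_mean_px=12000.0, area_sd_px=1100.0, texture_corr_len_px=3.0,
        foci_density=1.5, foci_contrast=0.15,
    ),
    "treated_d9": ConditionParams(
        area_mean_px=12000.0, area_sd_px=1100.0, texture_corr_len_px=3.0,
        foci_density=1.5, foci_contrast=0.15,
    ),
}


@dataclass
class SceneTruth:
    """Ground truth attached to every generated image or scene."""

    nucleus_masks: list[np.ndarray]
    condition: str
    qc_label: str  # "good" | "bad"
    texture_params: ConditionParams | None
    rng_seed: int
    bad_mode: str | None = None
    centroids: list[tuple[float, float]] = field(default_factory=list)
    scene_image: np.ndarray | None = None  # reference 2D scene (overviews)

    def __post_init__(self) -> None:
        # masks must be pairwise disjoint
        if len(self.nucleus_masks) > 1:
            total = np.zeros_like(self.nucleus_masks[0], dtype=np.int32)
            for m in self.nucleus_masks:
                total += m.astype(np.int32)
            if (total > 1).any():
                raise ValueError("ground-truth nucleus masks must be disjoint")

    @property
    def mask(self) -> np.ndarray:
        """Union of all nucleus masks (all-False raster if none)."""
        if not self.nucleus_masks:
            raise ValueError("no nucleus masks present")
        out = self.nucleus_masks[0].copy()
        for m in self.nucleus_masks[1:]:
            out |= m
        return out


# ---------------------------------------------------------------------------
# drawing primitives
# ---------------------------------------------------------------------------


def _ellipse_mask(shape, center, a, b, theta) -> np.ndarray:
    """Boolean mask of a rotated ellipse (semi-axes a, b), clipped to frame."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ct, st = math.cos(theta), math.sin(theta)
    u = dc * ct + dr * st
    v = -dc * st + dr * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _sample_geometry(
    params: ConditionParams,
    rng: np.random.Generator,
    aspect_range: tuple[float, float] = (0.75, 1.0),
):
    """Sample (area, semi-major a, semi-minor b, orientation)."""
    area = max(500.0, rng.normal(params.area_mean_px, params.area_sd_px))
    aspect = rng.uniform(*aspect_range)  # b / a
    a = math.sqrt(area / (math.pi * aspect))
    b = a * aspect
    theta = rng.uniform(0.0, math.pi)
    return area, a, b, theta


def _paint_interior(
    canvas: np.ndarray,
    mask: np.ndarray,
    params: ConditionParams,
    rng: np.random.Generator,
    pixel_size_nm: float,
) -> None:
    """Fill ``mask`` on ``canvas`` with a textured nuclear interior."""
    shape = canvas.shape
    interior = np.ones(shape)
    if np.isfinite(params.texture_corr_len_px):
        fld = ndimage.gaussian_filter(
            rng.standard_normal(shape), params.texture_corr_len_px
        )
        s = fld[mask].std() if mask.any() else 0.0
        if s > 0:
            interior = interior + fld * (TEXTURE_AMPLITUDE / s)
    else:
        rng.standard_normal(shape)  # keep the stream layout stable
    # heterochromatin-like bright foci
    area_px = int(mask.sum())
    area_um2 = area_px * (pixel_size_nm / 1000.0) ** 2
    lam = params.foci_density * area_um2
    n_foci = int(rng.poisson(lam)) if lam > 0 else 0
    if n_foci > 0 and area_px > 0:
        coords = np.argwhere(mask)
        picks = coords[rng.integers(0, len(coords), size=n_foci)]
        foci = np.zeros(shape, dtype=bool)
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        for r0, c0 in picks:
            foci |= (rr - r0) ** 2 + (cc - c0) ** 2 <= FOCUS_RADIUS_PX**2
        interior = interior + params.foci_contrast * (foci & mask)
    interior = np.clip(interior, 0.05, None)
    canvas[mask] = interior[mask]


def _finalize(
    canvas: np.ndarray,
    params: ConditionParams,
    rng: np.random.Generator,
    pixel_size_nm: float,
) -> Image2D:
    """Apply intensity scale and signal-proportional noise; wrap up."""
    img = canvas * params.intensity_scale
    if params.noise_sd > 0:
        sd = params.noise_sd * np.sqrt(np.maximum(img, 0.0) / params.intensity_scale)
        img = img + rng.standard_normal(img.shape) * sd * params.intensity_scale
    return Image2D(np.clip(img, 0.0, None), pixel_size_nm=pixel_size_nm)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_nucleus_detail(
    params: ConditionParams,
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    pixel_size_nm: float = 25.0,
    condition: str = "unspecified",
    aspect_range: tuple[float, float] = (0.75, 1.0),
) -> tuple[Image2D, SceneTruth]:
    """One centered, complete, in-focus nucleus on a quiet background.

    ``aspect_range`` bounds the minor/major axis ratio of the elliptical
    nucleus ((1, 1) forces circles).  Raises :class:`NucleusSizingError`
    when the sampled nucleus (plus a safety margin) cannot fit in
    ``shape``.
    """
    if shape[0] < 128 or shape[1] < 128:
        raise ValueError("detail frames must be at least 128 x 128")
    rng = stream(seed, "detail")
    _, a, b, theta = _sample_geometry(params, rng, aspect_range)
    if 2 * a + FIT_MARGIN_PX > min(shape):
        raise NucleusSizingError(
            f"nucleus major axis {2 * a:.0f} px does not fit in frame {shape}"
        )
    center = (shape[0] / 2.0, shape[1] / 2.0)
    mask = _ellipse_mask(shape, center, a, b, theta)
    canvas = np.full(shape, params.background_level)
    _paint_interior(canvas, mask, params, rng, pixel_size_nm)
    img = _finalize(canvas, params, rng, pixel_size_nm)
    truth = SceneTruth(
        nucleus_masks=[mask], condition=condition, qc_label="good",
        texture_params=params, rng_seed=seed, centroids=[center],
    )
    return img, truth


def generate_bad_detail(
    mode: str,
    seed: int = 0,
    params: ConditionParams | None = None,
    shape: tuple[int, int] = (256, 256),
    pixel_size_nm: float = 25.0,
    condition: str = "unspecified",
) -> tuple[Image2D, SceneTruth]:
    """A labeled failure-mode detail image (always ``qc_label == 'bad'``)."""
    if mode not in BAD_MODES:
        raise ValueError(f"unknown bad-image mode {mode!r}; valid: {BAD_MODES}")
    params = params or CONDITION_DEFAULTS["proliferating"]
    rng = stream(seed, "bad", mode)

    if mode == "out_of_focus":
        img, truth = generate_nucleus_detail(
            params, shape, seed=substream_seed(seed, "bad-base"),
            pixel_size_nm=pixel_size_nm, condition=condition,
        )
        blurred = ndimage.gaussian_filter(img.pixels, 8.0)
        img = Image2D(blurred, pixel_size_nm=pixel_size_nm)
        masks = truth.nucleus_masks

    elif mode == "truncated":
        _, a, b, theta = _sample_geometry(params, rng)
        # centre pushed to the frame edge: roughly half the nucleus is lost
        center = (shape[0] / 2.0, max(1.0, 0.05 * a))
        mask = _ellipse_mask(shape, center, a, b, theta)
        canvas = np.full(shape, params.background_level)
        _paint_interior(canvas, mask, params, rng, pixel_size_nm)
        img = _finalize(canvas, params, rng, pixel_size_nm)
        masks = [mask]

    elif mode == "blank_rows":
        img, truth = generate_nucleus_detail(
            params, shape, seed=substream_seed(seed, "bad-base"),
            pixel_size_nm=pixel_size_nm, condition=condition,
        )
        n_blank = max(int(math.ceil(0.12 * shape[0])), int(0.1 * shape[0]) + 1)
        start = int(rng.integers(0, shape[0] - n_blank + 1))
        pix = img.pixels.copy()
        pix[start : start + n_blank, :] = 0.0
        img = Image2D(pix, pixel_size_nm=pixel_size_nm)
        masks = truth.nucleus_masks

    elif mode == "empty":
        canvas = np.full(shape, params.background_level)
        img = _finalize(canvas, params, rng, pixel_size_nm)
        masks = []

    else:  # doublet
        _, a1, b1, th1 = _sample_geometry(params, rng)
        _, a2, b2, th2 = _sample_geometry(params, rng)
        # centres on the frame diagonal, major axes perpendicular to it so
        # the pair fits; residual overlap is carved from the second mask
        diag = math.atan2(shape[0], shape[1])
        c1 = (shape[0] * 0.32, shape[1] * 0.32)
        c2 = (shape[0] * 0.68, shape[1] * 0.68)
        m1 = _ellipse_mask(shape, c1, a1, b1, diag + math.pi / 2)
        m2 = _ellipse_mask(shape, c2, a2, b2, diag + math.pi / 2)
        m2 &= ~m1
        canvas = np.full(shape, params.background_level)
        _paint_interior(canvas, m1, params, rng, pixel_size_nm)
        _paint_interior(canvas, m2, params, rng, pixel_size_nm)
        img = _finalize(canvas, params, rng, pixel_size_nm)
        masks = [m1, m2]

    truth = SceneTruth(
        nucleus_masks=masks, condition=condition, qc_label="bad",
        texture_params=params, rng_seed=seed, bad_mode=mode,
    )
    return img, truth


def spiral_order(n_rows: int, n_cols: int) -> list[tuple[int, int]]:
    """Grid positions in a centre-out clockwise spiral (acquisition order)."""
    r, c = n_rows // 2, n_cols // 2
    out = []
    seen = set()

    def visit(rr, cc):
        if 0 <= rr < n_rows and 0 <= cc < n_cols and (rr, cc) not in seen:
            seen.add((rr, cc))
            out.append((rr, cc))

    visit(r, c)
    step = 1
    # right, down, left, up with growing run lengths
    moves = [(0, 1), (1, 0), (0, -1), (-1, 0)]
    mi = 0
    while len(out) < n_rows * n_cols:
        for _ in range(2):
            dr, dc = moves[mi % 4]
            for _ in range(step):
                r, c = r + dr, c + dc
                visit(r, c)
            mi += 1
        step += 1
    return out


def generate_overview_scene(
    n_nuclei: int,
    params: ConditionParams,
    tile_shape: tuple[int, int] = (256, 256),
    grid: tuple[int, int] = (2, 2),
    overlap_fraction: float = 0.2,
    seed: int = 0,
    pixel_size_nm: float = 100.0,
    condition: str = "unspecified",
    max_tries: int = 500,
    aspect_range: tuple[float, float] = (0.75, 1.0),
) -> tuple[TileSet, SceneTruth]:
    """A tiled 3-plane overview scene with ``n_nuclei`` planted nuclei.

    One global 3-plane stack (defocused / sharp / defocused) is built and
    then cut into spiral-ordered tiles with the requested overlap, so each
    tile's max-projection is exactly a crop of the reference 2D scene stored
    in the returned truth (``scene_image``).
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    if not (0.0 <= overlap_fraction <= 0.5):
        raise ValueError("overlap_fraction must lie in [0, 0.5]")
    rng = stream(seed, "overview")
    th, tw = tile_shape
    step_r = max(1, int(round(th * (1 - overlap_fraction))))
    step_c = max(1, int(round(tw * (1 - overlap_fraction))))
    scene_shape = (step_r * (grid[0] - 1) + th, step_c * (grid[1] - 1) + tw)

    # --- place nuclei without overlap
    placed: list[tuple[tuple[float, float], float, float, float, float]] = []
    for _ in range(n_nuclei):
        _, a, b, theta = _sample_geometry(params, rng, aspect_range)
        for attempt in range(max_tries):
            r0 = rng.uniform(a + FIT_MARGIN_PX, scene_shape[0] - a - FIT_MARGIN_PX)
            c0 = rng.uniform(a + FIT_MARGIN_PX, scene_shape[1] - a - FIT_MARGIN_PX)
            ok = all(
                math.hypot(r0 - pr, c0 - pc) > a + pa + 4
                for (pr, pc), pa, _, _, _ in placed
            )
            if ok:
                placed.append(((r0, c0), a, b, theta, attempt))
                break
        else:
            raise PlacementError(
                f"could not place nucleus {len(placed) + 1}/{n_nuclei} "
                f"in a {scene_shape} scene"
            )

    sharp_clean = np.full(scene_shape, params.background_level)
    masks, centroids = [], []
    for (r0, c0), a, b, theta, _ in placed:
        mask = _ellipse_mask(scene_shape, (r0, c0), a, b, theta)
        _paint_interior(sharp_clean, mask, params, rng, pixel_size_nm)
        masks.append(mask)
        centroids.append((r0, c0))

    defocus_clean = (
        ndimage.gaussian_filter(sharp_clean, DEFOCUS_SIGMA_PX) * DEFOCUS_ATTENUATION
        + params.background_level * (1 - DEFOCUS_ATTENUATION)
    )
    planes = []
    for clean in (defocus_clean, sharp_clean, defocus_clean):
        planes.append(_finalize(clean.copy(), params, rng, pixel_size_nm).pixels)
    scene_2d = np.maximum.reduce(planes)

    # --- cut into tiles
    tiles, coords = [], []
    for gr, gc in spiral_order(*grid):
        r0, c0 = gr * step_r, gc * step_c
        stack = ImageStack(
            planes=[
                Image2D(pl[r0 : r0 + th, c0 : c0 + tw], pixel_size_nm=pixel_size_nm)
                for pl in planes
            ]
        )
        tiles.append(stack)
        coords.append((c0 * pixel_size_nm, r0 * pixel_size_nm))

    tileset = TileSet(
        tiles=tiles, stage_coords=coords,
        overlap_fraction=overlap_fraction, pixel_size_nm=pixel_size_nm,
    )
    truth = SceneTruth(
        nucleus_masks=masks, condition=condition, qc_label="good",
        texture_params=params, rng_seed=seed, centroids=centroids,
        scene_image=scene_2d,
    )
    return tileset, truth


def generate_population(
    n_cells_per_condition: int,
    conditions: Sequence[str] = ("proliferating", "senescent"),
    seed: int = 0,
    bad_fraction: float = 0.2,
    shape: tuple[int, int] = (256, 256),
    pixel_size_nm: float = 25.0,
    condition_params: dict[str, ConditionParams] | None = None,
) -> tuple[list[Image2D], list[SceneTruth]]:
    """Balanced per-condition detail images with bad images mixed in.

    ``bad_fraction`` is the fraction of the *total* population that is bad,
    so ``n_bad = round(f / (1 - f) * n_good)``.  Bad images cycle through
    the five failure modes and through the condition parameter sets.
    """
    if n_cells_per_condition < 1:
        raise ValueError("n_cells_per_condition must be >= 1")
    if not (0.0 <= bad_fraction < 1.0):
        raise ValueError("bad_fraction must lie in [0, 1)")
    cp = dict(CONDITION_DEFAULTS)
    if condition_params:
        cp.update(condition_params)
    images, truths = [], []
    for ci, cond in enumerate(conditions):
        params = cp[cond]
        for j in range(n_cells_per_condition):
            s = substream_seed(seed, "pop-good", ci, j)
            img, truth = generate_nucleus_detail(
                params, shape=shape, seed=s, pixel_size_nm=pixel_size_nm,
                condition=cond,
            )
            images.append(img)
            truths.append(truth)
    n_good = n_cells_per_condition * len(conditions)
    n_bad = int(round(bad_fraction / (1.0 - bad_fraction) * n_good))
    for j in range(n_bad):
        mode = BAD_MODES[j % len(BAD_MODES)]
        cond = conditions[j % len(conditions)]
        s = substream_seed(seed, "pop-bad", j)
        img, truth = generate_bad_detail(
            mode, seed=s, params=cp[cond], shape=shape,
            pixel_size_nm=pixel_size_nm, condition=cond,
        )
        images.append(img)
        truths.append(truth)
    return images, truths
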