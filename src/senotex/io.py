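"""HDF5 / TIFF / CSV persistence for scenes, detail images and models.

The HDF5 layout mirrors the acquisition container used by automated
microscopes of this kind::

    /tiles/<i>/stack        3D array (planes, rows, cols)
    /tiles/<i>/stage_xy     (x_nm, y_nm)
    /details/<j>/image      2D array
    /truth/<j>/mask_<k>     boolean rasters
    /truth/<j>/labels       attrs: condition, qc_label, bad_mode, seed
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import tifffile

from .synthesis import Image2D, ImageStack, SceneTruth, TileSet

__all__ = [
    "write_details_h5",
    "read_details_h5",
    "write_tileset_h5",
    "read_tileset_h5",
    "write_tile_tiffs",
    "save_model_bundle",
    "load_model_bundle",
]


def _write_truth(grp: h5py.Group, truth: SceneTruth) -> None:
    for k, m in enumerate(truth.nucleus_masks):
        grp.create_dataset(f"mask_{k}", data=m.astype(np.uint8), compression="gzip")
    lab = grp.create_group("labels")
    lab.attrs["condition"] = truth.condition
    lab.attrs["qc_label"] = truth.qc_label
    lab.attrs["bad_mode"] = truth.bad_mode or ""
    lab.attrs["seed"] = truth.rng_seed


def _read_truth(grp: h5py.Group) -> SceneTruth:
    masks = [
        grp[k][()].astype(bool) for k in sorted(grp.keys()) if k.startswith("mask_")
    ]
    lab = grp["labels"].attrs
    return SceneTruth(
        nucleus_masks=masks,
        condition=str(lab["condition"]),
        qc_label=str(lab["qc_label"]),
        texture_params=None,
        rng_seed=int(lab["seed"]),
        bad_mode=str(lab["bad_mode"]) or None,
    )


def write_details_h5(
    path, images: Sequence[Image2D], truths: Sequence[SceneTruth]
) -> None:
    with h5py.File(path, "w") as f:
        for j, (img, truth) in enumerate(zip(images, truths)):
            g = f.create_group(f"details/{j}")
            d = g.create_dataset("image", data=img.pixels, compression="gzip")
            d.attrs["pixel_size_nm"] = img.pixel_size_nm
            _write_truth(f.create_group(f"truth/{j}"), truth)


def read_details_h5(path):
    images, truths = [], []
    with h5py.File(path, "r") as f:
        keys = sorted(f["details"].keys(), key=int)
        for j in keys:
            d = f[f"details/{j}/image"]
            images.append(
                Image2D(d[()], pixel_size_nm=float(d.attrs["pixel_size_nm"]))
            )
            truths.append(_read_truth(f[f"truth/{j}"]))
    return images, truths


def write_tileset_h5(path, tiles: TileSet, truth: SceneTruth | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["overlap_fraction"] = tiles.overlap_fraction
        f.attrs["pixel_size_nm"] = tiles.pixel_size_nm
        for i, (stack, xy) in enumerate(zip(tiles.tiles, tiles.stage_coords)):
            g = f.create_group(f"tiles/{i}")
            arr = np.stack([p.pixels for p in stack.planes])
            g.create_dataset("stack", data=arr, compression="gzip")
            g.create_dataset("stage_xy", data=np.asarray(xy, dtype=np.float64))
            g.attrs["z_step_nm"] = stack.z_step_nm
        if truth is not None:
            _write_truth(f.create_group("truth/0"), truth)
            if truth.scene_image is not None:
                f.create_dataset(
                    "truth/0/scene_image", data=truth.scene_image, compression="gzip"
                )


def read_tileset_h5(path) -> TileSet:
    with h5py.File(path, "r") as f:
        psz = float(f.attrs["pixel_size_nm"])
        tiles, coords = [], []
        for i in sorted(f["tiles"].keys(), key=int):
            g = f[f"tiles/{i}"]
            arr = g["stack"][()]
            tiles.append(
                ImageStack(
                    planes=[Image2D(pl, pixel_size_nm=psz) for pl in arr],
                    z_step_nm=float(g.attrs["z_step_nm"]),
                )
            )
            coords.append(tuple(g["stage_xy"][()]))
        return TileSet(
            tiles=tiles, stage_coords=coords,
            overlap_fraction=float(f.attrs["overlap_fraction"]), pixel_size_nm=psz,
        )


def write_tile_tiffs(directory, tiles: TileSet, prefix: str = "tile") -> list[Path]:
    """One multi-page TIFF per tile; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, stack in enumerate(tiles.tiles):
        arr = np.stack([p.pixels for p in stack.planes]).astype(np.float32)
        path = directory / f"{prefix}_{i:03d}.tif"
        tifffile.imwrite(path, arr, photometric="minisblack")
        paths.append(path)
    return paths


def save_model_bundle(path, payload: dict, manifest: dict) -> None:
    """Versioned model archive: a zip with a JSON manifest + joblib pickle."""
    import joblib

    buf = _io.BytesIO()
    joblib.dump(payload, buf)
    manifest = {"schema_version": 1, **manifest}
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as z:
        z.writestr("manifest.json", json.dumps(manifest, indent=2, sort_keys=True))
        z.writestr("model.joblib", buf.getvalue())


def load_model_bundle(path) -> tuple[dict, dict]:
    import joblib

    with zipfile.ZipFile(path, "r") as z:
        manifest = json.loads(z.read("manifest.json"))
        payload = joblib.load(_io.BytesIO(z.read("model.joblib")))
    return payload, manifest
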