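"""File formats: multi-page TIFF scenes, label masks, CSV tables, manifests.

Scenes are written as one multi-page 16-bit TIFF per field of view (one page
per channel, channel name in the page description), next to a per-scene
ground-truth CSV; a dataset-level ``manifest.json`` records the profile,
seed and per-scene conditions.  Feature tables are CSV with a column-metadata
JSON side-car (name, group, units).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import catalog
from .synthetic import MultiChannelImage, SceneRecord


def write_scene(out_dir: str | Path, rec: SceneRecord) -> dict:
    """Write one scene (image TIFF, mask TIFFs, ground-truth CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_path = out / f"{rec.scene_id}.tif"
    with tifffile.TiffWriter(img_path) as tif:
        for name, channel in rec.image.channels.items():
            tif.write(
                channel,
                description=name,
                resolution=(1e4 / rec.image.pixel_size_um,) * 2,
                resolutionunit="CENTIMETER",
            )
    masks_path = out / f"{rec.scene_id}_masks.tif"
    with tifffile.TiffWriter(masks_path) as tif:
        tif.write(rec.ground_truth.cell_labels.astype(np.uint16), description="CELL_LABELS")
        tif.write(rec.ground_truth.nucleus_labels.astype(np.uint16), description="NUCLEUS_LABELS")
    gt_path = out / f"{rec.scene_id}_groundtruth.csv"
    rec.ground_truth.table.to_csv(gt_path, index=False)
    return {
        "scene_id": rec.scene_id,
        "stiffness_kpa": rec.stiffness_kpa,
        "staining_group": rec.staining_group,
        "image": img_path.name,
        "masks": masks_path.name,
        "ground_truth": gt_path.name,
    }


def read_scene(
    scene_dir: str | Path, entry: dict
) -> tuple[MultiChannelImage, dict[str, np.ndarray]]:
    """Read one scene back from a manifest entry: (image, {mask name: mask})."""
    scene_dir = Path(scene_dir)
    channels: dict[str, np.ndarray] = {}
    pixel_size = 1.0
    with tifffile.TiffFile(scene_dir / entry["image"]) as tif:
        for page in tif.pages:
            name = (page.description or f"ch{len(channels)}").strip()
            channels[name] = page.asarray()
            res = page.tags.get("XResolution")
            if res is not None:
                num, den = res.value
                pixel_size = 1e4 * den / num
    masks: dict[str, np.ndarray] = {}
    with tifffile.TiffFile(scene_dir / entry["masks"]) as tif:
        for page in tif.pages:
            masks[(page.description or "MASK").strip()] = page.asarray().astype(np.int32)
    return MultiChannelImage(channels=channels, pixel_size_um=pixel_size), masks


def write_manifest(out_dir: str | Path, manifest: dict) -> Path:
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=_json_default))
    return path


def read_manifest(in_dir: str | Path) -> dict:
    return json.loads((Path(in_dir) / "manifest.json").read_text())


def write_feature_table(out_path: str | Path, table: pd.DataFrame) -> Path:
    """Feature CSV plus a column-metadata JSON side-car."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_path, index=False)
    meta = [
        {
            "name": c,
            "group": _column_group(c),
            "units": _column_units(c),
        }
        for c in table.columns
    ]
    out_path.with_suffix(".columns.json").write_text(
        json.dumps({"catalog_version": catalog.CATALOG_VERSION, "columns": meta}, indent=2)
    )
    return out_path


def _column_group(name: str) -> str:
    if name in catalog.METADATA_COLUMNS:
        return "metadata"
    if name.startswith(("cell_zernike",)):
        return "shape-zernike"
    if name.startswith(("cell_", "nucleus_", "cyto_")):
        return "shape"
    if name.startswith("ctx_"):
        return "context"
    if name in catalog.ENGINEERED_FEATURES:
        return "engineered"
    if name in catalog.CROSS_CHANNEL_FEATURES:
        return "marker-cross"
    return "marker"


def _column_units(name: str) -> str:
    if name.endswith(("_area", "area_um2", "convex_area")):
        return "um^2"
    if name.endswith(
        (
            "perimeter",
            "_dist",
            "diameter",
            "axis_length",
            "feret_max",
            "feret_min",
            "radius_mean",
            "radius_median",
            "radius_max",
            "radius_min",
            "radius_sd",
            "bbox_height",
            "bbox_width",
            "polarity",
            "_um",
        )
    ):
        return "um"
    return "dimensionless"


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
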