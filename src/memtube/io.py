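"""Shared file I/O: TIFF images, label maps, object/ratio CSVs, JSON sidecars.

Intensities are never rescaled on load; all quantification downstream
depends on raw units. Pixel size travels in a JSON payload stored in the
TIFF ImageDescription tag (written by :func:`write_image`) and can always
be overridden explicitly. A missing pixel size is an error, never a
silent default.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from memtube.pixelclass import LabelMap, ObjectRecord, ShapeCriteria
from memtube.profilequant import FlatFilmCalibration
from memtube.synthgen import FluorImage
from memtube.tubstats import TubulationResult

__all__ = [
    "read_image",
    "write_image",
    "read_label_map",
    "write_label_map",
    "objects_to_csv",
    "objects_from_csv",
    "results_to_csv",
    "write_calibration",
    "read_calibration",
]

OBJECT_COLUMNS = [
    "component_id",
    "cls",
    "area_px",
    "area_nm2",
    "major_axis_nm",
    "minor_axis_nm",
    "elongation",
    "skeleton_length_nm",
    "mean_width_nm",
]


def write_image(path: str | Path, image: FluorImage) -> None:
    """Write a 32-bit float grayscale TIFF with pixel size in the description tag."""
    desc = json.dumps({"pixel_size_nm": image.pixel_size_nm, "channel": image.channel})
    tifffile.imwrite(str(path), image.pixels.astype(np.float32), description=desc)


def read_image(
    path: str | Path, pixel_size_nm: float | None = None, channel: str | None = None
) -> FluorImage:
    """Read a grayscale TIFF (8/16/32-bit) as float, never rescaled.

    Raises on RGB/multi-page input and on a missing pixel size (supply the
    override if the file carries no metadata).
    """
    with tifffile.TiffFile(str(path)) as tf:
        if len(tf.pages) != 1:
            raise ValueError(f"{path}: expected a single-page TIFF, got {len(tf.pages)} pages")
        page = tf.pages[0]
        data = page.asarray()
        meta: dict = {}
        if page.description:
            try:
                meta = json.loads(page.description)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a 2D grayscale image, got shape {data.shape}")
    px = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
    if px is None:
        raise ValueError(
            f"{path}: pixel size not found in metadata and no override supplied"
        )
    ch = channel if channel is not None else meta.get("channel", "lipid")
    return FluorImage(pixels=data.astype(float), pixel_size_nm=float(px), channel=ch)


def write_label_map(path: str | Path, labels: LabelMap) -> None:
    desc = json.dumps({"pixel_size_nm": labels.pixel_size_nm, "classifier_id": labels.classifier_id})
    tifffile.imwrite(str(path), labels.labels.astype(np.uint8), description=desc)


def read_label_map(path: str | Path, pixel_size_nm: float | None = None) -> LabelMap:
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        data = page.asarray()
        meta = {}
        if page.description:
            try:
                meta = json.loads(page.description)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    px = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
    if px is None:
        raise ValueError(f"{path}: pixel size not found for label map")
    return LabelMap(labels=data, pixel_size_nm=float(px), classifier_id=meta.get("classifier_id", ""))


def objects_to_csv(path: str | Path, objects: list[ObjectRecord]) -> None:
    df = pd.DataFrame([asdict(o) for o in objects], columns=OBJECT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6g")


def objects_from_csv(path: str | Path) -> list[ObjectRecord]:
    df = pd.read_csv(path)
    return [ObjectRecord(**{c: row[c] for c in OBJECT_COLUMNS}) for _, row in df.iterrows()]


def results_to_csv(path: str | Path, results: list[TubulationResult]) -> None:
    rows = [
        {
            "image_id": r.image_id,
            "tubule_area_nm2": r.tubule_area_nm2,
            "vesicle_area_nm2": r.vesicle_area_nm2,
            "ratio": r.ratio if r.defined else "",
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.8g")


def write_calibration(path: str | Path, calib: FlatFilmCalibration) -> None:
    Path(path).write_text(json.dumps(asdict(calib), indent=2) + "\n")


def read_calibration(path: str | Path) -> FlatFilmCalibration:
    data = json.loads(Path(path).read_text())
    data["roi"] = tuple(data["roi"])
    return FlatFilmCalibration(**data)


def criteria_from_dict(data: dict) -> ShapeCriteria:
    allowed = set(ShapeCriteria.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown shape-criteria keys: {sorted(unknown)}")
    return ShapeCriteria(**data)
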