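"""On-disk formats: 8-bit PNG images and label images, CSV tables, JSON
sidecars.  Stages of the pipeline communicate only through these formats, so
real clinical masks and metadata tables can be substituted for phantom
outputs at any stage boundary."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .features import FeatureTable, feature_schema
from .segmentation import validate_label_image

__all__ = [
    "write_image", "read_image", "write_labels", "read_labels",
    "write_truth", "read_truth", "write_feature_table", "read_feature_table",
    "write_metadata", "read_metadata",
]


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def read_image(path: str | Path) -> np.ndarray:
    img = iio.imread(Path(path))
    if img.ndim == 3:  # collapse accidental RGB
        img = img[..., 0]
    return np.asarray(img, dtype=np.uint8)


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    iio.imwrite(Path(path), validate_label_image(labels))


def read_labels(path: str | Path) -> np.ndarray:
    return validate_label_image(read_image(path))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_truth(path: str | Path, truth: dict) -> None:
    """Analytic geometry truth of one phantom, as JSON."""
    Path(path).write_text(json.dumps(_jsonable(truth), indent=1))


def read_truth(path: str | Path) -> dict:
    truth = json.loads(Path(path).read_text())
    for region in truth.values():
        region["center"] = np.asarray(region["center"], dtype=float)
        region["semi_axes"] = tuple(region["semi_axes"])
        region["fourier_cos"] = np.asarray(region["fourier_cos"], dtype=float)
        region["fourier_sin"] = np.asarray(region["fourier_sin"], dtype=float)
    return truth


def write_metadata(path: str | Path, records) -> None:
    """Per-oocyte clinical metadata CSV."""
    pd.DataFrame([{
        "oocyte_id": r.oocyte_id, "patient_id": r.patient_id,
        "cycle_id": r.cycle_id, "clinic": r.clinic,
        "oocyte_age": r.oocyte_age, "outcome": r.outcome,
    } for r in records]).to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"oocyte_id": str, "patient_id": str,
                                    "cycle_id": str, "clinic": str})


def write_feature_table(table: FeatureTable, csv_path: str | Path) -> None:
    """Feature table as CSV plus a JSON sidecar schema (column -> tags)."""
    csv_path = Path(csv_path)
    table.data.to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".schema.json")
    sidecar.write_text(json.dumps(
        {c: {"group": m["group"], "regions": list(m["regions"])}
         for c, m in table.schema.items()}, indent=1))


def read_feature_table(csv_path: str | Path) -> FeatureTable:
    csv_path = Path(csv_path)
    data = pd.read_csv(csv_path, dtype={"oocyte_id": str, "patient_id": str,
                                        "cycle_id": str, "clinic": str})
    sidecar = csv_path.with_suffix(".schema.json")
    if sidecar.exists():
        raw = json.loads(sidecar.read_text())
        schema = {c: {"group": m["group"], "regions": tuple(m["regions"])}
                  for c, m in raw.items()}
    else:
        schema = feature_schema()
    schema = {c: m for c, m in schema.items() if c in data.columns}
    return FeatureTable(data=data, schema=schema)
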