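"""Format round-tripping: GeoJSON detections, CSV tables, images, configs.

Detections are exported as a GeoJSON FeatureCollection compatible with
digital-pathology viewers: one Feature per cell whose geometry is the cell
boundary, with the nucleus geometry, classification name and measurements
nested in ``properties``. Coordinates are micrometres.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from shapely.geometry import Polygon, mapping, shape

from .segmentation import CellClass, CellDetection
from .stain import StainModel

__all__ = [
    "detections_to_geojson",
    "geojson_to_detections",
    "write_geojson",
    "read_geojson",
    "detections_to_dataframe",
    "read_image",
    "write_image",
    "save_stain_model",
    "load_stain_model",
    "read_roi",
]


def detections_to_geojson(detections: list[CellDetection]) -> dict:
    features = []
    for det in detections:
        features.append(
            {
                "type": "Feature",
                "id": det.id,
                "geometry": mapping(det.cell_polygon),
                "properties": {
                    "objectType": "cell",
                    "classification": {"name": CellClass(det.class_label).value},
                    "nucleusGeometry": mapping(det.nucleus_polygon),
                    "centroid": list(det.centroid),
                    "nucleus_area_um2": det.nucleus_area_um2,
                    "cell_area_um2": det.cell_area_um2,
                    "measurements": {k: float(v) for k, v in det.features.items()},
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def geojson_to_detections(doc: dict) -> list[CellDetection]:
    if doc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    detections = []
    for feat in doc.get("features", []):
        props = feat.get("properties", {})
        cell_poly = shape(feat["geometry"])
        nuc_poly = shape(props["nucleusGeometry"])
        detections.append(
            CellDetection(
                id=int(feat.get("id", len(detections))),
                nucleus_polygon=nuc_poly,
                cell_polygon=cell_poly,
                centroid=tuple(props.get("centroid", nuc_poly.centroid.coords[0])),
                nucleus_area_um2=float(props.get("nucleus_area_um2", nuc_poly.area)),
                cell_area_um2=float(props.get("cell_area_um2", cell_poly.area)),
                features=dict(props.get("measurements", {})),
                class_label=CellClass(
                    props.get("classification", {}).get("name", "UNCLASSIFIED")
                ),
            )
        )
    return detections


def write_geojson(detections: list[CellDetection], path: str | Path) -> None:
    Path(path).write_text(json.dumps(detections_to_geojson(detections)))


def read_geojson(path: str | Path) -> list[CellDetection]:
    text = Path(path).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(
            f"malformed GeoJSON in {path} at line {exc.lineno}, column {exc.colno}: "
            f"{exc.msg}"
        ) from exc
    return geojson_to_detections(doc)


def detections_to_dataframe(detections: list[CellDetection]) -> pd.DataFrame:
    """Flat measurement table: one row per cell."""
    rows = []
    for det in detections:
        row = {
            "cell_id": det.id,
            "class_label": CellClass(det.class_label).value,
            "x_um": det.centroid[0],
            "y_um": det.centroid[1],
            "nucleus_area_um2": det.nucleus_area_um2,
            "cell_area_um2": det.cell_area_um2,
        }
        row.update(det.features)
        rows.append(row)
    return pd.DataFrame(rows)


def read_roi(path: str | Path) -> Polygon:
    """Read a region-of-interest polygon from a GeoJSON file."""
    doc = json.loads(Path(path).read_text())
    if doc.get("type") == "FeatureCollection":
        geom = doc["features"][0]["geometry"]
    elif doc.get("type") == "Feature":
        geom = doc["geometry"]
    else:
        geom = doc
    poly = shape(geom)
    if poly.is_empty:
        raise ValueError(f"empty ROI geometry in {path}")
    return poly


def read_image(path: str | Path) -> np.ndarray:
    """Read an RGB PNG/TIFF image as an (H, W, 3) array."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path).convert("RGB"))
    except Exception as exc:
        raise IOError(f"could not read image {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"{path} is not an RGB image (shape {arr.shape})")
    return arr[:, :, :3]


def write_image(image: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        Image.fromarray(image).save(path)


def save_stain_model(model: StainModel, path: str | Path) -> None:
    """Write a stain model as a small structured text file (JSON)."""
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def load_stain_model(path: str | Path) -> StainModel:
    return StainModel.from_dict(json.loads(Path(path).read_text()))
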