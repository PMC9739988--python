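"""Per-cell intensity and shape measurements, plus neighbourhood smoothing.

For every detected cell we measure intensity statistics (mean, std, min, max)
of the hematoxylin and eosin OD in three compartments — nucleus, whole cell,
and cytoplasm (cell minus nucleus) — together with nucleus shape descriptors.
Smoothed variants average each measurement over neighbouring cells with
Gaussian distance weights, capturing local context (e.g. lymphocyte
aggregates) that single-cell measurements miss.

Feature tables are plain pandas DataFrames indexed by cell id with a stable
column order; they round-trip losslessly through CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from skimage import draw, measure

from .segmentation import CellDetection

__all__ = [
    "BASE_SHAPE_FEATURES",
    "compute_features",
    "smooth_features",
    "smoothed_column_name",
]

_COMPARTMENTS = ("nucleus", "cell", "cytoplasm")
_STAINS = ("hematoxylin", "eosin")
_STATS = ("mean", "std", "min", "max")

BASE_SHAPE_FEATURES = (
    "nucleus_area_um2",
    "nucleus_perimeter_um",
    "nucleus_circularity",
    "nucleus_eccentricity",
    "nucleus_max_caliper_um",
    "nucleus_min_caliper_um",
    "cell_area_um2",
    "nucleus_cell_area_ratio",
)

QC_COLUMNS = ("qc_cytoplasm_fallback",)


def smoothed_column_name(radius_um: float, base: str) -> str:
    return f"smoothed_{radius_um:g}um_{base}"


def _polygon_mask(poly: Polygon, shape: tuple[int, int], px: float) -> np.ndarray:
    ext = np.asarray(poly.exterior.coords)
    rr, cc = draw.polygon(ext[:, 1] / px, ext[:, 0] / px, shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _calipers(poly: Polygon) -> tuple[float, float]:
    """Max and min Feret diameters from the convex hull."""
    hull = poly.convex_hull
    if hull.geom_type != "Polygon":
        return 0.0, 0.0
    pts = np.asarray(hull.exterior.coords)[:-1]
    if len(pts) < 2:
        return 0.0, 0.0
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    max_cal = float(d.max())
    # Min caliper: smallest extent over directions normal to hull edges.
    edges = np.roll(pts, -1, axis=0) - pts
    lengths = np.linalg.norm(edges, axis=1)
    ok = lengths > 0
    normals = np.stack([-edges[ok, 1], edges[ok, 0]], axis=1) / lengths[ok, None]
    proj = pts @ normals.T
    min_cal = float((proj.max(axis=0) - proj.min(axis=0)).min())
    return max_cal, min_cal


def _eccentricity(mask: np.ndarray) -> float:
    props = measure.regionprops(mask.astype(np.uint8))
    if not props:
        return 0.0
    return float(props[0].eccentricity)


def _intensity_stats(values: np.ndarray) -> tuple[float, float, float, float]:
    if values.size == 0:
        return 0.0, 0.0, 0.0, 0.0
    return (
        float(values.mean()),
        float(values.std()),
        float(values.min()),
        float(values.max()),
    )


def compute_features(
    detections: list[CellDetection],
    hema_channel: np.ndarray,
    eosin_channel: np.ndarray,
    pixel_size_um: float = 0.5,
) -> pd.DataFrame:
    """Measure per-cell intensity and shape features.

    Parameters
    ----------
    detections : list of CellDetection
        Cells with valid nucleus and cell polygons (µm coordinates).
    hema_channel, eosin_channel : 2D ndarray
        Deconvolved stain-density rasters at ``pixel_size_um`` resolution.

    Returns
    -------
    DataFrame indexed by cell id. Cells whose cytoplasm ring is empty fall
    back to whole-cell intensity statistics, flagged in
    ``qc_cytoplasm_fallback``.
    """
    hema = np.asarray(hema_channel, dtype=float)
    eosin = np.asarray(eosin_channel, dtype=float)
    if hema.shape != eosin.shape:
        raise ValueError("stain channels must have identical shape")
    shape = hema.shape
    channels = {"hematoxylin": hema, "eosin": eosin}

    rows = []
    for det in detections:
        nuc_mask = _polygon_mask(det.nucleus_polygon, shape, pixel_size_um)
        cell_mask = _polygon_mask(det.cell_polygon, shape, pixel_size_um)
        cell_mask |= nuc_mask  # rasterization guard: nucleus is part of the cell
        cyto_mask = cell_mask & ~nuc_mask
        fallback = not cyto_mask.any()
        masks = {
            "nucleus": nuc_mask,
            "cell": cell_mask,
            "cytoplasm": cell_mask if fallback else cyto_mask,
        }
        row: dict[str, float] = {"cell_id": det.id}
        for comp in _COMPARTMENTS:
            for stain in _STAINS:
                stats = _intensity_stats(channels[stain][masks[comp]])
                for stat, val in zip(_STATS, stats):
                    row[f"{comp}_{stain}_{stat}"] = val
        area = det.nucleus_polygon.area
        perim = det.nucleus_polygon.exterior.length
        max_cal, min_cal = _calipers(det.nucleus_polygon)
        cell_area = det.cell_polygon.area
        row["nucleus_area_um2"] = area
        row["nucleus_perimeter_um"] = perim
        row["nucleus_circularity"] = (
            min(1.0, 4.0 * np.pi * area / perim**2) if perim > 0 else 0.0
        )
        row["nucleus_eccentricity"] = _eccentricity(nuc_mask)
        row["nucleus_max_caliper_um"] = max_cal
        row["nucleus_min_caliper_um"] = min_cal
        row["cell_area_um2"] = cell_area
        row["nucleus_cell_area_ratio"] = area / cell_area if cell_area > 0 else 1.0
        row["qc_cytoplasm_fallback"] = float(fallback)
        rows.append(row)

    columns = (
        [f"{c}_{s}_{t}" for c in _COMPARTMENTS for s in _STAINS for t in _STATS]
        + list(BASE_SHAPE_FEATURES)
        + list(QC_COLUMNS)
    )
    if not rows:
        return pd.DataFrame(columns=columns).rename_axis("cell_id")
    table = pd.DataFrame(rows).set_index("cell_id")[columns]
    if table.isna().any().any():
        raise AssertionError("feature table contains missing values")
    return table


def smooth_features(
    table: pd.DataFrame,
    centroids: np.ndarray,
    radius_um: float,
) -> pd.DataFrame:
    """Append Gaussian-smoothed neighbourhood variants of every base feature.

    For cell *i* the smoothed value of feature *f* is the weighted mean
    ``sum_j w_ij f_j / sum_j w_ij`` over cells within ``2 * radius_um``
    (including *i* itself), with ``w_ij = exp(-d_ij^2 / (2 sigma^2))`` and
    ``sigma = radius_um / 2``. Radius 0 copies the base values unchanged.
    """
    if radius_um < 0:
        raise ValueError("radius_um must be >= 0")
    pts = np.asarray(centroids, dtype=float)
    if pts.shape != (len(table), 2):
        raise ValueError("centroids must align with the table rows, shape (n, 2)")
    base_cols = [c for c in table.columns if c not in QC_COLUMNS and not c.startswith("smoothed_")]
    out = table.copy()
    if len(table) == 0:
        for col in base_cols:
            out[smoothed_column_name(radius_um, col)] = pd.Series(dtype=float)
        return out
    values = table[base_cols].to_numpy(dtype=float)
    if radius_um == 0:
        smoothed = values
    else:
        sigma = radius_um / 2.0
        tree = cKDTree(pts)
        pairs = tree.query_ball_tree(tree, r=2.0 * radius_um)
        smoothed = np.empty_like(values)
        for i, neigh in enumerate(pairs):
            idx = np.asarray(neigh)
            d2 = ((pts[idx] - pts[i]) ** 2).sum(axis=1)
            w = np.exp(-d2 / (2.0 * sigma**2))
            smoothed[i] = w @ values[idx] / w.sum()
    for k, col in enumerate(base_cols):
        out[smoothed_column_name(radius_um, col)] = smoothed[:, k]
    return out
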