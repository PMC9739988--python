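"""Watershed cell detection on the hematoxylin optical-density channel.

The detector mirrors the classical nucleus-detection recipe used in digital
pathology platforms: smooth the hematoxylin OD, threshold to a foreground
mask, split touching nuclei by watershed seeded from the maxima of the
background-corrected OD (morphological opening estimates the background),
filter by nucleus area and local background intensity, then grow a bounded
cell boundary around each nucleus with a distance-limited Voronoi expansion
so neighbouring cells never overlap.

All geometry is expressed in micrometres with the origin at the image
top-left, x rightward and y downward; polygon vertices sit at pixel centers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Point, Polygon
from skimage import measure, morphology, segmentation as skseg, transform
from skimage.feature import peak_local_max

logger = logging.getLogger(__name__)

__all__ = [
    "CellClass",
    "DetectionParams",
    "CellDetection",
    "resample_to_working_resolution",
    "detect_cells",
    "count_and_area",
]


class CellClass(str, Enum):
    """Cell classes used throughout the pipeline."""

    TUMOR = "TUMOR"
    IMMUNE = "IMMUNE"
    STROMA = "STROMA"
    IGNORE = "IGNORE"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class DetectionParams:
    """Watershed cell-detection parameters (micrometre units).

    Defaults are the standard H&E nucleus-detection settings at a 0.5 µm/px
    working resolution: background estimated by a grayscale opening of radius
    8 µm, Gaussian pre-smoothing with σ = 1.5 µm, nuclei kept when their area
    lies in [10, 400] µm² and the local background OD does not exceed 2, and
    each cell boundary obtained by expanding its nucleus 5 µm without
    overlapping neighbours.
    """

    requested_pixel_size_um: float = 0.5
    background_radius_um: float = 8.0
    median_radius_um: float = 0.0
    sigma_um: float = 1.5
    min_cell_area_um2: float = 10.0
    max_cell_area_um2: float = 400.0
    od_threshold: float = 0.1
    max_background_intensity: float = 2.0
    cell_expansion_um: float = 5.0
    min_seed_separation_um: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "requested_pixel_size_um",
            "background_radius_um",
            "median_radius_um",
            "sigma_um",
            "min_cell_area_um2",
            "max_cell_area_um2",
            "cell_expansion_um",
            "min_seed_separation_um",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.requested_pixel_size_um <= 0:
            raise ValueError("requested_pixel_size_um must be > 0")
        if not self.min_cell_area_um2 < self.max_cell_area_um2:
            raise ValueError("min_cell_area_um2 must be < max_cell_area_um2")
        if self.od_threshold <= 0:
            raise ValueError("od_threshold must be > 0")


@dataclass
class CellDetection:
    """One detected cell: nucleus and cell geometry plus measurements."""

    id: int
    nucleus_polygon: Polygon
    cell_polygon: Polygon
    centroid: tuple[float, float]  # (x, y) in µm
    nucleus_area_um2: float
    cell_area_um2: float
    features: dict[str, float] = field(default_factory=dict)
    class_label: CellClass = CellClass.UNCLASSIFIED


def resample_to_working_resolution(
    image: np.ndarray,
    source_pixel_size_um: float,
    requested_pixel_size_um: float = 0.5,
) -> np.ndarray:
    """Resample a raster to the working pixel size, preserving physical extent.

    Uses area-weighted (anti-aliased) interpolation. A warning is logged when
    upsampling by more than 4x, since resampling cannot create information.
    """
    if source_pixel_size_um <= 0 or requested_pixel_size_um <= 0:
        raise ValueError("pixel sizes must be positive")
    if source_pixel_size_um == requested_pixel_size_um:
        return image
    factor = source_pixel_size_um / requested_pixel_size_um
    if factor > 4.0:
        logger.warning(
            "upsampling by %.1fx (from %.3g to %.3g um/px); detail cannot be created",
            factor,
            source_pixel_size_um,
            requested_pixel_size_um,
        )
    out_shape = tuple(
        max(1, int(round(s * factor))) for s in image.shape[:2]
    ) + image.shape[2:]
    return transform.resize(
        image.astype(float),
        out_shape,
        order=1,
        mode="reflect",
        anti_aliasing=factor < 1.0,
        preserve_range=True,
    )


def _mask_to_polygon(mask: np.ndarray, pixel_size_um: float) -> Polygon | None:
    """Trace the outer boundary of a binary mask as a polygon in µm."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)  # outer boundary is the longest
    # (row, col) -> (x, y); subtract the pad offset.
    xy = np.stack([(contour[:, 1] - 1.0), (contour[:, 0] - 1.0)], axis=1)
    poly = Polygon(xy * pixel_size_um)
    if not poly.is_valid:
        poly = poly.buffer(0)
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
    return poly if not poly.is_empty else None


def detect_cells(
    hema_od: np.ndarray,
    params: DetectionParams | None = None,
    roi: Polygon | None = None,
) -> list[CellDetection]:
    """Detect and segment cells in a hematoxylin OD raster.

    Parameters
    ----------
    hema_od : 2D ndarray
        Hematoxylin optical density at ``params.requested_pixel_size_um``.
    params : DetectionParams
        Detection settings; defaults follow the standard H&E recipe.
    roi : shapely Polygon, optional
        Region of interest in µm; detections whose centroid falls outside
        are dropped. ``None`` analyses the full raster.

    Returns
    -------
    list of CellDetection, deterministically ordered by centroid (y, x).
    """
    params = params or DetectionParams()
    od = np.asarray(hema_od, dtype=float)
    if od.ndim != 2:
        raise ValueError("hema_od must be a 2D raster")
    if od.min() < 0:
        raise ValueError("raster contains negative values; expected OD units")
    if roi is not None and roi.is_empty:
        raise ValueError("roi is empty")
    px = params.requested_pixel_size_um

    work = od
    if params.median_radius_um > 0:
        r = max(1, int(round(params.median_radius_um / px)))
        work = ndi.median_filter(work, footprint=morphology.disk(r))
    if params.sigma_um > 0:
        work = ndi.gaussian_filter(work, sigma=params.sigma_um / px)

    # Background via grayscale opening: removes structures smaller than the
    # background radius, leaving slowly varying staining and artifacts.
    if params.background_radius_um > 0:
        r_bg = max(1, int(round(params.background_radius_um / px)))
        background = morphology.opening(work, morphology.disk(r_bg))
    else:
        background = np.zeros_like(work)
    corrected = np.clip(work - background, 0.0, None)

    # Foreground from the smoothed OD; the background-corrected image drives
    # seeding (suppressing broad background bumps) and the background filter.
    # Thresholding the uncorrected OD keeps oversized structures whole so the
    # maximum-area filter can reject them instead of their post-subtraction
    # remnants slipping through.
    mask = work > params.od_threshold
    if not mask.any():
        return []

    min_sep_px = max(1, int(round(params.min_seed_separation_um / px)))
    seeds = peak_local_max(
        corrected, min_distance=min_sep_px, labels=mask, exclude_border=False
    )
    if len(seeds) == 0:
        return []
    markers = np.zeros(corrected.shape, dtype=np.int32)
    # Raster-scan tie-break: seeds sorted by (row, col).
    order = np.lexsort((seeds[:, 1], seeds[:, 0]))
    for i, idx in enumerate(order, start=1):
        markers[tuple(seeds[idx])] = i
    labels = skseg.watershed(-corrected, markers=markers, mask=mask)

    # Fill holes so chromatin texture does not fragment nuclei.
    filled = np.zeros_like(labels)
    for region in measure.regionprops(labels):
        sl = region.slice
        m = labels[sl] == region.label
        filled[sl][ndi.binary_fill_holes(m)] = region.label
    labels = filled

    px_area = px * px
    keep: list[int] = []
    for region in measure.regionprops(labels):
        area = region.area * px_area
        if not params.min_cell_area_um2 <= area <= params.max_cell_area_um2:
            continue
        cy, cx = region.centroid
        if background[int(round(cy)), int(round(cx))] > params.max_background_intensity:
            continue
        keep.append(region.label)
    if not keep:
        return []
    relabel = np.zeros(labels.max() + 1, dtype=np.int32)
    for i, lab in enumerate(keep, start=1):
        relabel[lab] = i
    nuclei = relabel[labels]

    # Distance-limited Voronoi expansion: cells grow up to cell_expansion_um
    # but never into a neighbour.
    if params.cell_expansion_um > 0:
        cells = skseg.expand_labels(nuclei, distance=params.cell_expansion_um / px)
    else:
        cells = nuclei

    detections: list[CellDetection] = []
    nuc_props = {r.label: r for r in measure.regionprops(nuclei)}
    cell_props = {r.label: r for r in measure.regionprops(cells)}
    for lab, nprop in nuc_props.items():
        npoly = _mask_to_polygon(nuclei == lab, px)
        cprop = cell_props.get(lab)
        cpoly = _mask_to_polygon(cells == lab, px) if cprop is not None else None
        if npoly is None:
            continue
        if cpoly is None:
            cpoly = npoly
        cy, cx = nprop.centroid
        centroid = (cx * px, cy * px)
        if roi is not None and not roi.covers(Point(centroid)):
            continue
        detections.append(
            CellDetection(
                id=0,  # assigned after sorting
                nucleus_polygon=npoly,
                cell_polygon=cpoly,
                centroid=centroid,
                nucleus_area_um2=nprop.area * px_area,
                cell_area_um2=(cprop.area if cprop else nprop.area) * px_area,
            )
        )
    detections.sort(key=lambda d: (d.centroid[1], d.centroid[0]))
    for i, det in enumerate(detections):
        det.id = i
    return detections


def count_and_area(
    detections: list[CellDetection], roi: Polygon
) -> tuple[dict[str, int], float]:
    """Count detections per class and convert the ROI area to mm².

    Returns ``(counts, area_mm2)`` where counts is keyed by class name and
    includes every class (zero-filled).
    """
    counts = {c.value: 0 for c in CellClass}
    for det in detections:
        counts[CellClass(det.class_label).value] += 1
    area_mm2 = roi.area / 1e6  # µm² -> mm²
    return counts, area_mm2
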