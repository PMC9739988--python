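"""H&E stain handling: optical density conversion, stain-vector estimation,
and color deconvolution.

Light transmitted through a stained section follows the Beer-Lambert law, so
per-channel optical density ``OD = -log10(I / I0)`` is additive across stains.
Each stain is characterised by a unit 3-vector of per-channel absorbances; an
RGB pixel's OD is then a non-negative combination of the stain vectors, and
deconvolution inverts that 3x3 linear system to recover per-stain densities.

Stain vectors vary between slides and scanners, so they are estimated per
image from the plane spanned by foreground OD pixels (the automatic
plane-fitting / extreme-angle-percentile estimator that is standard for H&E).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ODImage",
    "StainModel",
    "DegenerateInputError",
    "rgb_to_od",
    "estimate_stain_vectors",
    "deconvolve",
    "compose",
    "default_background_intensity",
]


class DegenerateInputError(ValueError):
    """Raised when an image lacks the structure an estimator needs."""


@dataclass(frozen=True)
class ODImage:
    """Per-pixel, per-RGB-channel optical density (dimensionless, >= 0).

    Attributes
    ----------
    values : ndarray, shape (H, W, 3)
        Optical densities; finite and non-negative.
    pixel_size_um : float
        Physical edge length of one pixel in micrometres.
    """

    values: np.ndarray
    pixel_size_um: float = 0.5

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[2] != 3:
            raise ValueError(f"OD array must have shape (H, W, 3), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("OD values must be finite")
        if v.min() < 0:
            raise ValueError("OD values must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]


@dataclass(frozen=True)
class StainModel:
    """Unit OD direction vectors for hematoxylin, eosin and a residual.

    The residual is the normalized cross product of H and E, completing an
    invertible 3x3 basis so every OD pixel has a unique decomposition.
    """

    hematoxylin_vector: np.ndarray
    eosin_vector: np.ndarray
    residual_vector: np.ndarray = field(default=None)  # type: ignore[assignment]
    background_intensity: np.ndarray = field(
        default_factory=lambda: np.array([255.0, 255.0, 255.0])
    )

    def __post_init__(self) -> None:
        h = np.asarray(self.hematoxylin_vector, dtype=float).ravel()
        e = np.asarray(self.eosin_vector, dtype=float).ravel()
        if h.shape != (3,) or e.shape != (3,):
            raise ValueError("stain vectors must have 3 components")
        for name, v in (("hematoxylin", h), ("eosin", e)):
            n = np.linalg.norm(v)
            if abs(n - 1.0) > 1e-9:
                raise ValueError(f"{name} vector must be unit norm (got {n:.6g})")
        cosang = np.clip(abs(float(h @ e)), 0.0, 1.0)
        if np.degrees(np.arccos(cosang)) <= 1.0:
            raise ValueError("hematoxylin and eosin vectors are nearly collinear")
        r = self.residual_vector
        if r is None:
            r = np.cross(h, e)
            r = r / np.linalg.norm(r)
        else:
            r = np.asarray(r, dtype=float).ravel()
            if abs(np.linalg.norm(r) - 1.0) > 1e-9:
                raise ValueError("residual vector must be unit norm")
            if abs(r @ h) > 1e-6 or abs(r @ e) > 1e-6:
                raise ValueError("residual vector must be orthogonal to H and E")
        bg = np.asarray(self.background_intensity, dtype=float).ravel()
        if bg.shape == ():
            bg = np.full(3, float(bg))
        if bg.shape != (3,) or np.any(bg <= 0):
            raise ValueError("background_intensity must be 3 positive values")
        object.__setattr__(self, "hematoxylin_vector", h)
        object.__setattr__(self, "eosin_vector", e)
        object.__setattr__(self, "residual_vector", r)
        object.__setattr__(self, "background_intensity", bg)

    @property
    def matrix(self) -> np.ndarray:
        """Stain matrix with columns (H, E, residual)."""
        return np.stack(
            [self.hematoxylin_vector, self.eosin_vector, self.residual_vector], axis=1
        )

    def to_dict(self) -> dict:
        return {
            "hematoxylin": [float(x) for x in self.hematoxylin_vector],
            "eosin": [float(x) for x in self.eosin_vector],
            "residual": [float(x) for x in self.residual_vector],
            "background": [float(x) for x in self.background_intensity],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StainModel":
        return cls(
            hematoxylin_vector=np.array(d["hematoxylin"], dtype=float),
            eosin_vector=np.array(d["eosin"], dtype=float),
            residual_vector=np.array(d["residual"], dtype=float)
            if "residual" in d
            else None,
            background_intensity=np.array(d.get("background", [255.0] * 3)),
        )


def default_background_intensity(image: np.ndarray) -> np.ndarray:
    """Robust per-channel white-level estimate: the 99.9th-percentile intensity."""
    img = np.asarray(image, dtype=float)
    return np.percentile(img.reshape(-1, img.shape[-1]), 99.9, axis=0)


def rgb_to_od(
    image: np.ndarray,
    background_intensity: np.ndarray | float | None = None,
    pixel_size_um: float = 0.5,
) -> ODImage:
    """Convert an RGB intensity raster to optical density.

    ``OD = -log10(max(I, 1) / I0)`` per channel, clipped to >= 0. The clamp at
    1 intensity count bounds the OD of fully absorbing pixels.

    Parameters
    ----------
    image : ndarray, shape (H, W, 3)
        RGB intensities in ``[0, background_intensity]``.
    background_intensity : scalar or length-3 array, optional
        Per-channel white level ``I0``; estimated from the image
        (99.9th-percentile per channel) when omitted.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected RGB image of shape (H, W, 3), got {img.shape}")
    if background_intensity is None:
        bg = default_background_intensity(img)
    else:
        bg = np.broadcast_to(np.asarray(background_intensity, dtype=float), (3,)).copy()
    if np.any(bg <= 0):
        raise ValueError("background intensity must be positive")
    od = -np.log10(np.maximum(img, 1.0) / bg)
    od = np.clip(od, 0.0, None)
    return ODImage(values=od, pixel_size_um=pixel_size_um)


def estimate_stain_vectors(
    od: ODImage,
    od_min: float = 0.15,
    angle_percentile: float = 1.0,
    background_intensity: np.ndarray | None = None,
    min_foreground_pixels: int = 100,
) -> StainModel:
    """Estimate H&E stain vectors from the dominant plane of foreground OD.

    Foreground pixels (total OD above ``od_min``) are projected onto the plane
    of their two leading singular vectors; the stain vectors are taken at the
    ``angle_percentile`` / ``100 - angle_percentile`` extremes of the angular
    distribution in that plane. Hematoxylin is identified as the vector with
    the larger blue-channel absorbance.

    Raises
    ------
    DegenerateInputError
        If fewer than ``min_foreground_pixels`` pixels exceed ``od_min``, or
        the OD cloud is effectively one-dimensional (a single stain).
    """
    if not 0 < angle_percentile < 50:
        raise ValueError("angle_percentile must be in (0, 50)")
    pix = od.values.reshape(-1, 3)
    fg = pix[pix.sum(axis=1) > od_min]
    if fg.shape[0] < min_foreground_pixels:
        raise DegenerateInputError(
            f"only {fg.shape[0]} foreground pixels above OD {od_min} "
            f"(need >= {min_foreground_pixels})"
        )
    # Plane fit through the origin: OD mixtures of two stains live in the span
    # of the two stain vectors, so no centering before the SVD.
    _, s, vt = np.linalg.svd(fg, full_matrices=False)
    if s[0] <= 0 or s[1] / s[0] < 1e-4:
        raise DegenerateInputError(
            "OD cloud is rank 1 (single stain direction); the second "
            "principal direction is collapsed"
        )
    basis = vt[:2]  # rows: two principal directions
    # Orient the basis so projections land in the first/second quadrant.
    proj = fg @ basis.T
    for k in range(2):
        if np.median(proj[:, k]) < 0:
            basis[k] = -basis[k]
            proj[:, k] = -proj[:, k]
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(angles, [angle_percentile, 100.0 - angle_percentile])
    v_lo = np.cos(lo) * basis[0] + np.sin(lo) * basis[1]
    v_hi = np.cos(hi) * basis[0] + np.sin(hi) * basis[1]
    vecs = []
    for v in (v_lo, v_hi):
        if v.sum() < 0:  # absorbance directions are non-negative overall
            v = -v
        vecs.append(v / np.linalg.norm(v))
    # Hematoxylin absorbs most in... red/green, appearing blue; its OD vector
    # has the larger blue component relative to eosin's.
    if vecs[0][2] >= vecs[1][2]:
        h, e = vecs[0], vecs[1]
    else:
        h, e = vecs[1], vecs[0]
    bg = (
        np.array([255.0, 255.0, 255.0])
        if background_intensity is None
        else np.asarray(background_intensity, dtype=float)
    )
    return StainModel(hematoxylin_vector=h, eosin_vector=e, background_intensity=bg)


def deconvolve(
    od: ODImage | np.ndarray, model: StainModel, clip: bool = True
) -> np.ndarray:
    """Unmix an OD image into (hematoxylin, eosin, residual) density channels.

    Solves the per-pixel 3x3 system ``OD = M c``; negative densities are
    clipped to zero unless ``clip=False``. Returns an array of shape
    (H, W, 3) with the channel order (hematoxylin, eosin, residual).
    """
    m = model.matrix
    if abs(np.linalg.det(m)) < 1e-12:
        raise ValueError("stain matrix is singular")
    values = od.values if isinstance(od, ODImage) else np.asarray(od, dtype=float)
    conc = values @ np.linalg.inv(m).T
    return np.clip(conc, 0.0, None) if clip else conc


def compose(concentrations: np.ndarray, model: StainModel) -> np.ndarray:
    """Forward Beer-Lambert mixing: stain densities -> per-channel OD array.

    The exact linear forward model: no clipping is applied, so
    ``deconvolve(compose(c, M), M, clip=False)`` recovers ``c`` for any
    loading (a large residual loading can produce nonphysical negative OD).
    """
    return np.asarray(concentrations, dtype=float) @ model.matrix.T
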