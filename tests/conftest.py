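"""Shared fixtures: small rendered tiles and their detection products.

The expensive artifacts (a rendered default tile and its detections) are
session-scoped so segmentation, feature and pipeline tests share one
computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import cKDTree

from tilquant.segmentation import DetectionParams, detect_cells
from tilquant.stain import deconvolve, rgb_to_od
from tilquant.synthetic import SceneSpec, default_stain_model, generate_tile


@pytest.fixture(scope="session")
def stain_model():
    return default_stain_model()


@pytest.fixture(scope="session")
def default_tile():
    """Default 320 µm tile: 100 tumor + 60 immune + 40 stroma nuclei."""
    spec = SceneSpec(seed=1)
    image, truth = generate_tile(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def tile_channels(default_tile, stain_model):
    _, image, _ = default_tile
    od = rgb_to_od(image, 255.0)
    return deconvolve(od, stain_model)


@pytest.fixture(scope="session")
def tile_detections(tile_channels):
    return detect_cells(tile_channels[:, :, 0], DetectionParams())


def greedy_match(detections, truth, max_dist_um=3.0):
    """Unique nearest-centroid matching; returns {truth_row: detection_idx}."""
    tree = cKDTree(truth[["x_um", "y_um"]].to_numpy())
    centroids = np.array([d.centroid for d in detections])
    dist, idx = tree.query(centroids)
    matches = {}
    for k in np.argsort(dist):
        if dist[k] <= max_dist_um and idx[k] not in matches:
            matches[int(idx[k])] = int(k)
    return matches
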