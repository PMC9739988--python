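"""Estimate H&E stain vectors from a synthetic tile and unmix the channels.

Renders a tile with a known stain matrix, re-estimates the stain vectors
from the image alone, and reports the angular error plus the deconvolved
channel magnitudes.
"""

import numpy as np

from tilquant import deconvolve, estimate_stain_vectors, generate_tile, rgb_to_od
from tilquant.synthetic import SceneSpec, default_stain_model


def angle_deg(u, v):
    return np.degrees(np.arccos(np.clip(abs(float(u @ v)), 0, 1)))


def main():
    truth_model = default_stain_model()
    image, _ = generate_tile(SceneSpec(seed=1))
    od = rgb_to_od(image, background_intensity=255.0)
    est = estimate_stain_vectors(od)

    print("estimated hematoxylin OD vector:", np.round(est.hematoxylin_vector, 3))
    print("estimated eosin OD vector:      ", np.round(est.eosin_vector, 3))
    print(
        "angular error vs rendering truth: "
        f"H {angle_deg(est.hematoxylin_vector, truth_model.hematoxylin_vector):.2f} deg, "
        f"E {angle_deg(est.eosin_vector, truth_model.eosin_vector):.2f} deg"
    )
    channels = deconvolve(od, est)
    print(
        f"hematoxylin channel: mean {channels[:, :, 0].mean():.3f} OD, "
        f"max {channels[:, :, 0].max():.3f} OD"
    )
    print(
        "Hematoxylin is recovered within a few degrees; the faint cytoplasmic "
        "eosin (never near-pure in this scene) is harder to pin down. The "
        "hematoxylin channel now isolates nuclear density for detection."
    )


if __name__ == "__main__":
    main()
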