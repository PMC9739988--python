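"""End-to-end orchestration: pixels to hazard ratios.

``run_pipeline`` executes the full analysis flow for a set of tumor-region
images: per-image stain estimation and deconvolution, watershed cell
detection, feature measurement with neighbourhood smoothing, cell
classification, TILs scoring, then cohort-level cut-point discovery and Cox
survival modelling against a clinical table. Every run writes a manifest
(config hash, seed, package versions) sufficient to reproduce its outputs.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from . import __version__
from .classifier import TrainedCellClassifier, classify_cells
from .config import PipelineConfig
from .cutpoint import CutpointResult, find_optimal_cutpoint
from .features import compute_features, smooth_features
from .io import detections_to_dataframe, write_geojson
from .segmentation import CellClass, count_and_area, detect_cells
from .stain import deconvolve, estimate_stain_vectors, rgb_to_od
from .survival import SurvivalCohort, run_table2_models
from .tils import TILsReport, compute_tils_report

logger = logging.getLogger(__name__)

__all__ = ["PipelineStageError", "score_image", "run_pipeline"]


class PipelineStageError(RuntimeError):
    """A stage failure, carrying the stage name and the offending input id."""

    def __init__(self, stage: str, input_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on input {input_id!r}: {cause}")
        self.stage = stage
        self.input_id = input_id
        self.cause = cause


@dataclass
class ImageScore:
    """Per-image analysis products."""

    detections: list
    feature_table: pd.DataFrame
    report: TILsReport


def score_image(
    image: np.ndarray,
    roi: Polygon | None,
    classifier: TrainedCellClassifier | None,
    config: PipelineConfig,
    input_id: str = "<image>",
    oracle_labels: pd.Series | None = None,
) -> ImageScore:
    """Run stain -> detection -> features -> classification -> TILs on one image.

    ``oracle_labels`` (class per detection id) bypasses the classifier, for
    ground-truth pipeline validation.
    """
    px = config.detection.requested_pixel_size_um
    try:
        od = rgb_to_od(image, config.stain.background_intensity, pixel_size_um=px)
        model = estimate_stain_vectors(
            od, od_min=config.stain.od_min,
            angle_percentile=config.stain.angle_percentile,
        )
        channels = deconvolve(od, model)
    except Exception as exc:
        raise PipelineStageError("stain", input_id, exc) from exc

    if roi is None:
        h, w = image.shape[:2]
        roi = box(0.0, 0.0, w * px, h * px)
    try:
        detections = detect_cells(channels[:, :, 0], config.detection, roi)
    except Exception as exc:
        raise PipelineStageError("segment", input_id, exc) from exc

    try:
        table = compute_features(
            detections, channels[:, :, 0], channels[:, :, 1], pixel_size_um=px
        )
        centroids = np.array([d.centroid for d in detections]).reshape(-1, 2)
        for radius in config.features.smoothing_radii_um:
            table = smooth_features(table, centroids, radius)
    except Exception as exc:
        raise PipelineStageError("features", input_id, exc) from exc

    try:
        if oracle_labels is not None:
            labels = oracle_labels.reindex(table.index).fillna("UNCLASSIFIED")
        elif classifier is not None:
            labels, _ = classify_cells(classifier, table)
        else:
            labels = pd.Series("UNCLASSIFIED", index=table.index)
        for det in detections:
            det.class_label = CellClass(labels.loc[det.id])
            det.features = table.loc[det.id].to_dict()
    except Exception as exc:
        raise PipelineStageError("classify", input_id, exc) from exc

    counts, area_mm2 = count_and_area(detections, roi)
    report = compute_tils_report(
        counts, area_mm2, config.tils.include_ignore_in_total
    )
    return ImageScore(detections=detections, feature_table=table, report=report)


def run_pipeline(
    images: dict[str, tuple[np.ndarray, Polygon | None]],
    clinical: pd.DataFrame,
    config: PipelineConfig | None = None,
    classifier: TrainedCellClassifier | None = None,
    oracle_labels: dict[str, pd.Series] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Execute the full flow and (optionally) write artifacts to ``out_dir``.

    Parameters
    ----------
    images : mapping patient_id -> (RGB image, roi polygon or None)
    clinical : DataFrame with patient_id, time_months, event and covariates.
    classifier : trained cell classifier; ``oracle_labels`` may replace it.

    Returns
    -------
    dict with ``tils`` (per-patient DataFrame), ``cutpoint``
    (CutpointResult), ``survival`` (Table-2-style model dict) and
    ``manifest``.
    """
    config = config or PipelineConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    rows = []
    for pid in sorted(images):
        image, roi = images[pid]
        score = score_image(
            image, roi, classifier, config, input_id=pid,
            oracle_labels=None if oracle_labels is None else oracle_labels.get(pid),
        )
        row = {"patient_id": pid, **score.report.to_row()}
        rows.append(row)
        if out is not None:
            write_geojson(score.detections, out / f"{pid}.cells.geojson")
            detections_to_dataframe(score.detections).to_csv(
                out / f"{pid}.cells.csv", index=False
            )
    tils_df = pd.DataFrame(rows)
    if out is not None:
        tils_df.to_csv(out / "tils.csv", index=False)

    overlap = [
        c for c in clinical.columns if c != "patient_id" and c in tils_df.columns
    ]
    if overlap:
        logger.info("pipeline-computed columns replace clinical ones: %s", overlap)
    merged = clinical.drop(columns=overlap).merge(
        tils_df, on="patient_id", how="inner"
    )
    cohort = SurvivalCohort(merged)
    variable = config.cutpoint.variable
    try:
        cut: CutpointResult | None = find_optimal_cutpoint(
            merged[variable].to_numpy(),
            cohort.times,
            cohort.events,
            min_group_fraction=config.cutpoint.min_group_fraction,
            correction=config.cutpoint.correction,
            seed=config.seed,
        )
    except ValueError as exc:
        logger.warning("cut-point search failed: %s", exc)
        cut = None
    threshold = cut.threshold if cut is not None else config.survival.etils_threshold
    try:
        models = run_table2_models(
            cohort,
            etils_variable=variable,
            etils_threshold=threshold,
            ties=config.survival.ties,
        )
    except ValueError as exc:
        logger.warning("survival modelling skipped: %s", exc)
        models = None

    manifest = {
        "tilquant_version": __version__,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "seed": config.seed,
        "python": platform.python_version(),
        "n_images": len(images),
        "n_patients": len(merged),
    }
    if out is not None:
        if cut is not None:
            (out / "cutpoint.json").write_text(
                json.dumps(
                    {
                        "threshold": cut.threshold,
                        "chi_square": cut.chi_square,
                        "p_raw": cut.p_raw,
                        "p_corrected": cut.p_corrected,
                        "n_low": cut.n_low,
                        "n_high": cut.n_high,
                    }
                )
            )
            pd.DataFrame(cut.scan, columns=["candidate", "chi_square"]).to_csv(
                out / "cutpoint_scan.csv", index=False
            )
        if models is not None:
            models["multivariate"].summary.to_csv(out / "cox_multivariate.csv")
            pd.concat(
                {k: v.summary for k, v in models["univariate"].items()},
                names=["factor"],
            ).to_csv(out / "cox_univariate.csv")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "tils": tils_df,
        "cutpoint": cut,
        "survival": models,
        "manifest": manifest,
    }
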