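"""End-to-end per-case pipeline: QC -> (annotate | predict) -> score -> regions.

Stage order is fixed: noise QC on the descending-aorta mask; optional median
denoising (std > 36 HU) or exclusion (std > 45 HU); cylinder ROI either
expanded from a disk annotation or predicted by the network on the isotropic
crop and mapped back; Agatston scoring and severity binning on the
acquisition-space volume; optional sub-ROI analysis.  Excluded cases carry a
record but no scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .geometry import (
    CylinderParams,
    DiskAnnotation,
    expand_disk_to_cylinder,
    fit_local_frame,
    parameterize_cylinder_mask,
    reconstruct_cylinder_mask,
)
from .qc import aorta_noise, median_denoise, resample_crop, window_normalize
from .scoring import ScoreReport, score_roi
from .subroi import RegionalReport, partition, regional_scores, sector_boundaries
from .volume import ImageVolume

logger = logging.getLogger(__name__)

__all__ = ["CaseRecord", "run_pipeline", "cohort_summary"]


@dataclass
class CaseRecord:
    """Everything the pipeline produced for one case."""

    case_id: str
    qc_status: str
    cylinder_source: str = ""  # "annotated" | "predicted" | "" when excluded
    params: CylinderParams | None = None
    report: ScoreReport | None = None
    regional: RegionalReport | None = None
    sex: str = "unknown"
    origin_fallback: bool = False

    def to_row(self) -> dict:
        row = {
            "case_id": self.case_id,
            "qc_status": self.qc_status,
            "cylinder_source": self.cylinder_source,
            "sex": self.sex,
        }
        if self.report is not None:
            row.update(self.report.to_dict())
        return row


def run_pipeline(
    case_id: str,
    vol: ImageVolume,
    aorta_mask: np.ndarray,
    *,
    disk: DiskAnnotation | None = None,
    model=None,
    heart_bounds_mm: np.ndarray | None = None,
    sex: str = "unknown",
    config: PipelineConfig | None = None,
    with_regional: bool = False,
) -> CaseRecord:
    """Run one case through the full pipeline (annotate or predict path)."""
    cfg = config or PipelineConfig()
    noise = aorta_noise(vol, aorta_mask, cfg.qc)
    logger.info("%s: aorta noise %.1f HU -> %s", case_id, noise.std_hu, noise.status)
    if noise.status == "exclude":
        return CaseRecord(case_id=case_id, qc_status="exclude", sex=sex)
    if noise.status == "denoise":
        vol = median_denoise(vol)
        logger.info("%s: applied 3x3 median filter", case_id)

    frame = None
    fallback = False
    if disk is not None:
        frame = fit_local_frame(disk, vol.spacing)
        mask = expand_disk_to_cylinder(disk, frame, cfg.expansion, vol)
        params = parameterize_cylinder_mask(mask, vol)
        params = CylinderParams(
            normal=params.normal,
            origin_mm=params.origin_mm,
            radius_mm=params.radius_mm,
            height_mm=params.height_mm,
        )
        source = "annotated"
    elif model is not None:
        from .nn.train import predict_cylinder, prepare_case  # lazy: heavy import

        if heart_bounds_mm is None:
            raise ValueError("predict path needs heart bounds")
        iso, crop = resample_crop(
            vol, heart_bounds_mm, out_shape=model.config.input_shape, iso_spacing_mm=cfg.iso_spacing_mm
        )
        img = window_normalize(iso, cfg.window_hu).values
        params, fallback = predict_cylinder(model, img, crop)
        mask = reconstruct_cylinder_mask(params, vol)
        source = "predicted"
    else:
        raise ValueError("provide either a disk annotation or a model")

    report = score_roi(
        vol, mask, sex=sex, calibration=cfg.mass_calibration, policy=cfg.severity,
        qc_status=noise.status,
    )
    record = CaseRecord(
        case_id=case_id,
        qc_status=noise.status,
        cylinder_source=source,
        params=params,
        report=report,
        sex=sex,
        origin_fallback=fallback,
    )
    if with_regional:
        sectors = None
        pc1 = None
        if disk is not None and disk.anchors and frame is not None:
            sectors = sector_boundaries(
                disk.anchors, frame, vol.spacing, axis_origin_mm=params.origin_mm,
                mode=cfg.sector_mode,
            )
            pc1 = frame.pc1
        part = partition(mask, params, vol, sectors=sectors, frame_pc1=pc1)
        record.regional = regional_scores(vol, part)
    return record


def cohort_summary(records: list[CaseRecord], config: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-case table plus severity-bin histogram columns."""
    cfg = config or PipelineConfig()
    df = pd.DataFrame([r.to_row() for r in records])
    if "severity_bin" in df:
        counts = df["severity_bin"].value_counts()
        for lab in cfg.severity.bin_labels:
            df.attrs[f"bin_{lab}"] = int(counts.get(lab, 0))
    df.attrs["n_excluded"] = int((df["qc_status"] == "exclude").sum()) if len(df) else 0
    return df
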