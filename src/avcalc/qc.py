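"""Noise QC, denoising, intensity normalization and isotropic crop.

CT calcium-score exams reconstructed with sharp kernels or acquired at low
exposure can be noisy enough (streaks from photon starvation) to create false
calcifications.  Noise is quantified as the standard deviation of
sub-threshold (< 130 HU) voxels inside an externally supplied
descending-aorta mask: above 36 HU the case is flagged for slice-wise 3x3
median denoising, above 45 HU it is excluded from automated analysis.

Model inputs are windowed to [-300, 100] HU, rescaled to [0, 1], resampled to
1 mm isotropic voxels and cropped to a fixed window (176 x 176 x 128 by
default) centered on the heart-sac bounding box; the crop geometry is
recorded so predictions can be mapped back, because calcification metrics are
always computed on the acquisition-space volume, never the resample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import GridCrop
from .scoring import HU_THRESHOLD
from .volume import ImageVolume

logger = logging.getLogger(__name__)

__all__ = [
    "NoiseReport",
    "QcThresholds",
    "aorta_noise",
    "median_denoise",
    "window_normalize",
    "resample_crop",
    "soft_tissue_bounds",
]

WINDOW_HU = (-300.0, 100.0)


@dataclass
class QcThresholds:
    """Aorta-noise decision thresholds (HU std of sub-130-HU voxels)."""

    std_denoise: float = 36.0
    std_exclude: float = 45.0


@dataclass
class NoiseReport:
    """Noise statistics over the descending-aorta mask and the QC verdict."""

    mean_hu: float
    std_hu: float
    status: str  # clean | denoise | exclude
    n_voxels: int

    def to_dict(self) -> dict:
        return {
            "mean_hu": self.mean_hu,
            "std_hu": self.std_hu,
            "status": self.status,
            "n_voxels": self.n_voxels,
        }


def aorta_noise(
    vol: ImageVolume, aorta_mask: np.ndarray, thresholds: QcThresholds | None = None
) -> NoiseReport:
    """Noise statistics over aorta voxels below 130 HU (excluding candidate
    calcifications), with status clean / denoise (> 36) / exclude (> 45)."""
    thresholds = thresholds or QcThresholds()
    if aorta_mask.shape != vol.values.shape:
        raise ValueError("aorta mask shape does not match the volume")
    if not aorta_mask.any():
        raise ValueError("aorta mask is empty")
    vals = vol.values[aorta_mask.astype(bool)]
    vals = vals[vals < HU_THRESHOLD]
    if vals.size == 0:
        raise ValueError("no aorta voxels below 130 HU; cannot assess noise")
    std = float(vals.std())
    if std > thresholds.std_exclude:
        status = "exclude"
    elif std > thresholds.std_denoise:
        status = "denoise"
    else:
        status = "clean"
    return NoiseReport(mean_hu=float(vals.mean()), std_hu=std, status=status, n_voxels=int(vals.size))


def median_denoise(vol: ImageVolume) -> ImageVolume:
    """Slice-wise 2D 3x3 median filter (suited to streak artifacts)."""
    out = ndimage.median_filter(vol.values, size=(3, 3, 1), mode="nearest")
    return vol.like(out.astype(vol.values.dtype))


def window_normalize(vol: ImageVolume, window: tuple[float, float] = WINDOW_HU) -> ImageVolume:
    """Clip to the HU window and affinely rescale to [0, 1]."""
    lo, hi = window
    out = (np.clip(vol.values, lo, hi) - lo) / (hi - lo)
    return vol.like(out.astype(np.float32))


def soft_tissue_bounds(vol: ImageVolume, lo_hu: float = -200.0, hi_hu: float = 200.0) -> np.ndarray:
    """Fallback heart window: bounding box (mm) of the largest soft-tissue
    connected component.  Returns (2, 3) [min_mm, max_mm].  Used for phantoms
    when no external heart-sac mask is available."""
    from skimage.measure import label as cc_label

    m = (vol.values > lo_hu) & (vol.values < hi_hu)
    lab = cc_label(m)
    if lab.max() == 0:
        raise ValueError("no soft-tissue component found for heart bounds")
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    comp = lab == counts.argmax()
    idx = np.argwhere(comp)
    return np.stack([vol.index_to_mm(idx.min(axis=0)), vol.index_to_mm(idx.max(axis=0))])


def resample_crop(
    vol: ImageVolume,
    heart_bounds_mm: np.ndarray,
    out_shape: tuple[int, int, int] = (176, 176, 128),
    iso_spacing_mm: float = 1.0,
    is_mask: bool = False,
) -> tuple[ImageVolume, GridCrop]:
    """Resample to isotropic voxels and crop a fixed window on the heart.

    The isotropic grid shares the acquisition origin; the crop window is
    centered on the heart bounding box (clamped toward the volume when it can
    be, padded with the global minimum where it cannot).  Linear
    interpolation for images, nearest for masks.  Returns the cropped volume
    and the :class:`GridCrop` needed to map coordinates back.
    """
    heart_bounds_mm = np.asarray(heart_bounds_mm, dtype=float)
    if heart_bounds_mm.shape != (2, 3) or np.any(heart_bounds_mm[1] < heart_bounds_mm[0]):
        raise ValueError("heart bounds must be (2, 3) [min_mm, max_mm] with min <= max")
    center_mm = heart_bounds_mm.mean(axis=0)
    center_iso = (center_mm - np.asarray(vol.origin_mm)) / iso_spacing_mm
    offset = np.round(center_iso - np.asarray(out_shape) / 2.0).astype(int)

    # iso sample positions, expressed as fractional acquisition indices
    axes_idx = [
        (
            (offset[a] + np.arange(out_shape[a], dtype=float)) * iso_spacing_mm
        )
        / vol.spacing[a]
        for a in range(3)
    ]
    coords = np.meshgrid(*axes_idx, indexing="ij")
    fill = float(vol.values.min())
    out = ndimage.map_coordinates(
        vol.values.astype(np.float32),
        np.stack([c.ravel() for c in coords]),
        order=0 if is_mask else 1,
        mode="constant",
        cval=fill,
    ).reshape(out_shape)
    if np.any(offset < 0) or np.any(
        (offset + np.asarray(out_shape)) * iso_spacing_mm
        > np.asarray(vol.shape) * np.asarray(vol.spacing)
    ):
        logger.info("crop window under-filled by the volume; padded with %.1f", fill)

    crop = GridCrop(
        crop_offset=tuple(int(o) for o in offset),
        crop_shape=tuple(out_shape),
        orig_shape=vol.shape,
        orig_spacing=vol.spacing,
        orig_origin_mm=vol.origin_mm,
        iso_spacing_mm=iso_spacing_mm,
    )
    iso = ImageVolume(
        out,
        (iso_spacing_mm,) * 3,
        tuple(np.asarray(vol.origin_mm) + offset * iso_spacing_mm),
    )
    return iso, crop
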