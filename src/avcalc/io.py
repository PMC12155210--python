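"""Readers and writers: NIfTI / DICOM-series volumes, masks, reports."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np

from .volume import ImageVolume

logger = logging.getLogger(__name__)

__all__ = ["read_volume", "write_nifti", "read_nifti_mask", "write_mask", "write_report_json"]


def read_volume(path: str | Path) -> ImageVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    Values are HU (DICOM rescale slope/intercept applied); axis order is
    (x, y, z) with z the slice axis; spacing from the headers.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    return _read_nifti(path)


def _read_nifti(path: Path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float32)  # scl slope/inter applied
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or invalid voxel spacing in header")
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    return ImageVolume(data, tuple(float(z) for z in zooms), origin)


def _read_dicom_series(path: Path) -> ImageVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", "") and p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:  # non-DICOM stray file
            continue
        if hasattr(ds, "ImagePositionPatient"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM slices found in {path}")
    orientations = {tuple(np.round(np.asarray(s.ImageOrientationPatient, float), 4)) for s in slices}
    if len(orientations) > 1:
        raise ValueError(f"{path}: mixed slice orientations in series")
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    gaps = np.diff(zs)
    if len(gaps) == 0:
        raise ValueError(f"{path}: series has a single slice")
    if np.ptp(gaps) > 0.01 * abs(gaps.mean()) + 1e-6:
        raise ValueError(f"{path}: non-uniform slice gaps ({gaps.min():.3f}-{gaps.max():.3f} mm)")
    ps = getattr(slices[0], "PixelSpacing", None)
    if ps is None:
        raise ValueError(f"{path}: missing PixelSpacing")
    sy, sx = float(ps[0]), float(ps[1])  # PixelSpacing is (row, col)
    sz = float(abs(gaps.mean()))
    vol = []
    for s in slices:
        slope = float(getattr(s, "RescaleSlope", 1.0))
        inter = float(getattr(s, "RescaleIntercept", 0.0))
        vol.append(s.pixel_array.astype(np.float32) * slope + inter)
    arr = np.stack(vol, axis=-1)  # (rows, cols, z) = (y, x, z)
    arr = np.transpose(arr, (1, 0, 2))  # -> (x, y, z)
    pos0 = np.asarray(slices[0].ImagePositionPatient, dtype=float)
    return ImageVolume(arr, (sx, sy, sz), (float(pos0[0]), float(pos0[1]), float(pos0[2])))


def write_nifti(vol: ImageVolume, path: str | Path) -> None:
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin_mm
    nib.save(nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), affine), str(path))


def write_mask(mask: np.ndarray, ref: ImageVolume, path: str | Path) -> None:
    """Binary or labeled mask as uint8 NIfTI on the reference geometry."""
    affine = np.diag(list(ref.spacing) + [1.0])
    affine[:3, 3] = ref.origin_mm
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def read_nifti_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()) > 0.5


def write_report_json(obj, path: str | Path) -> None:
    d = obj.to_dict() if hasattr(obj, "to_dict") else obj
    Path(path).write_text(json.dumps(d, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
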