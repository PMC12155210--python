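"""Agatston-criteria calcification scoring inside a valve ROI.

A calcified lesion is found per the clinical calcium-scoring convention:
voxels >= 130 HU inside the ROI are grouped into 2D connected components per
axial slice (8-neighbour), components below 1 mm^2 are discarded as noise, and
the surviving components are grouped across slices into 3D lesions
(26-neighbour).  Scores:

* Agatston — sum over slice-components of area (mm^2) times the 4-tier density
  weight (1/2/3/4 for max HU in [130,200) / [200,300) / [300,400) / >=400),
  computed on native slices with no slice-increment rescaling;
* volume — calcified voxel volume (mm^3) of qualifying lesions;
* mass — calibration x sum over lesions of mean HU x lesion volume (the
  calibration factor is scanner-specific; the default 0.001 is a placeholder);
* lesion count — 3D lesions whose individual Agatston score exceeds 10
  (strict), screening out residual noise.

Severity bins and sex-specific severe-AS flags follow the guideline
thresholds for the aortic-valve Agatston score (severe likely above 2000 in
men / 1200 in women; unlikely below 1600 / 800).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label

from .volume import ImageVolume

__all__ = [
    "CalcLesion",
    "ScoreReport",
    "SeverityPolicy",
    "min_area_voxels",
    "find_lesions",
    "agatston_score",
    "volume_score",
    "mass_score",
    "count_valid_lesions",
    "severity",
    "score_roi",
]

HU_THRESHOLD = 130.0
MIN_AREA_MM2 = 1.0


def density_weight(max_hu: float) -> int:
    """4-tier Agatston density weight from a component's maximum HU."""
    if max_hu >= 400:
        return 4
    if max_hu >= 300:
        return 3
    if max_hu >= 200:
        return 2
    return 1


@dataclass
class CalcLesion:
    """One 3D calcified lesion: its voxels and per-slice 2D components."""

    voxels: np.ndarray  # (n, 3) int indices
    slice_components: list[dict]  # each: {z, n_voxels, area_mm2, max_hu}
    agatston: float
    volume_mm3: float
    mean_hu: float


@dataclass
class ScoreReport:
    """Per-case calcification metrics and severity assignment."""

    agatston: float
    volume_mm3: float
    mass_mg: float
    n_valid_lesions: int
    n_lesions: int
    severity_bin: str = ""
    severe_flag: bool | None = None
    unlikely_severe_flag: bool | None = None
    qc_status: str = "clean"

    def to_dict(self) -> dict:
        return {
            "agatston": self.agatston,
            "volume_mm3": self.volume_mm3,
            "mass_mg": self.mass_mg,
            "n_valid_lesions": self.n_valid_lesions,
            "n_lesions": self.n_lesions,
            "severity_bin": self.severity_bin,
            "severe_flag": self.severe_flag,
            "unlikely_severe_flag": self.unlikely_severe_flag,
            "qc_status": self.qc_status,
        }


@dataclass
class SeverityPolicy:
    """Guideline Agatston bins and sex-specific severe-AS thresholds."""

    bin_edges: tuple[float, ...] = (0.0, 800.0, 1200.0, 2000.0)
    bin_labels: tuple[str, ...] = ("0", "1-800", "800-1200", "1200-2000", "2000+")
    severe_male: float = 2000.0
    severe_female: float = 1200.0
    unlikely_male: float = 1600.0
    unlikely_female: float = 800.0
    conservative_male: float = 1500.0
    conservative_female: float = 900.0
    valid_lesion_agatston: float = 10.0

    def __post_init__(self) -> None:
        if any(b >= a for b, a in zip(self.bin_edges[1:], self.bin_edges[2:])):
            raise ValueError("bin edges must be strictly increasing")


def min_area_voxels(in_plane_spacing: tuple[float, float]) -> int:
    """Smallest voxel count whose in-plane area reaches 1 mm^2.

    E.g. 7 voxels at 0.4 x 0.4 mm, 1 at 1.0 x 1.0 mm.
    """
    sx, sy = in_plane_spacing
    if sx <= 0 or sy <= 0:
        raise ValueError("spacing must be positive")
    return int(math.ceil(MIN_AREA_MM2 / (sx * sy) - 1e-9))


def find_lesions(vol: ImageVolume, roi_mask: np.ndarray) -> list[CalcLesion]:
    """Detect calcified lesions (>= 130 HU, >= 1 mm^2 per 2D slice component)
    inside the ROI and group them into 3D lesions."""
    if roi_mask.shape != vol.values.shape:
        raise ValueError(f"ROI mask shape {roi_mask.shape} != volume shape {vol.values.shape}")
    sx, sy, _ = vol.spacing
    area_per_voxel = sx * sy
    n_min = min_area_voxels((sx, sy))

    cand = (vol.values >= HU_THRESHOLD) & roi_mask.astype(bool)
    if not cand.any():
        return []

    # per-slice 8-connected components, drop those under 1 mm^2
    retained = np.zeros_like(cand)
    for z in range(cand.shape[2]):
        sl = cand[:, :, z]
        if not sl.any():
            continue
        lab = cc_label(sl, connectivity=2)
        counts = np.bincount(lab.ravel())
        keep = np.flatnonzero(counts >= n_min)
        keep = keep[keep != 0]
        if keep.size:
            retained[:, :, z] = np.isin(lab, keep)

    if not retained.any():
        return []

    lab3 = cc_label(retained, connectivity=3)  # 26-neighbour grouping
    lesions: list[CalcLesion] = []
    for li in range(1, lab3.max() + 1):
        comp = lab3 == li
        voxels = np.argwhere(comp)
        slice_components = []
        ag = 0.0
        for z in np.unique(voxels[:, 2]):
            sl = comp[:, :, z]
            lab2 = cc_label(sl, connectivity=2)
            for ci in range(1, lab2.max() + 1):
                m2 = lab2 == ci
                n = int(m2.sum())
                max_hu = float(vol.values[:, :, z][m2].max())
                area = n * area_per_voxel
                ag += area * density_weight(max_hu)
                slice_components.append(
                    {"z": int(z), "n_voxels": n, "area_mm2": area, "max_hu": max_hu}
                )
        vol_mm3 = voxels.shape[0] * vol.voxel_volume_mm3
        mean_hu = float(vol.values[comp].mean())
        lesions.append(CalcLesion(voxels, slice_components, ag, vol_mm3, mean_hu))
    return lesions


def agatston_score(lesions: list[CalcLesion]) -> float:
    """Total Agatston score (additive over lesions)."""
    return float(sum(l.agatston for l in lesions))


def volume_score(lesions: list[CalcLesion]) -> float:
    """Total calcified volume in mm^3 over qualifying lesions."""
    return float(sum(l.volume_mm3 for l in lesions))


def mass_score(lesions: list[CalcLesion], calibration: float = 0.001) -> float:
    """Mass score (mg): calibration x sum of (mean HU x lesion volume)."""
    if calibration <= 0:
        raise ValueError("mass calibration factor must be positive")
    return float(calibration * sum(l.mean_hu * l.volume_mm3 for l in lesions))


def count_valid_lesions(lesions: list[CalcLesion], threshold: float = 10.0) -> int:
    """Lesions whose individual Agatston score strictly exceeds `threshold`."""
    return int(sum(1 for l in lesions if l.agatston > threshold))


def severity(
    agatston: float, sex: str = "unknown", policy: SeverityPolicy | None = None
) -> tuple[str, bool | None, bool | None]:
    """Severity bin and sex-specific (severe, unlikely-severe) flags.

    Bins are {0, 1-800, 800-1200, 1200-2000, 2000+} with upper-inclusive
    edges; flags use strict > / < against the sex thresholds and are None for
    unknown sex.
    """
    if agatston < 0:
        raise ValueError("Agatston score cannot be negative")
    policy = policy or SeverityPolicy()
    if agatston == 0:
        b = policy.bin_labels[0]
    else:
        b = policy.bin_labels[int(np.searchsorted(policy.bin_edges, agatston, side="left"))]
    if sex == "male":
        return b, agatston > policy.severe_male, agatston < policy.unlikely_male
    if sex == "female":
        return b, agatston > policy.severe_female, agatston < policy.unlikely_female
    if sex == "unknown":
        return b, None, None
    raise ValueError(f"sex must be male/female/unknown, got {sex!r}")


def score_roi(
    vol: ImageVolume,
    roi_mask: np.ndarray,
    sex: str = "unknown",
    calibration: float = 0.001,
    policy: SeverityPolicy | None = None,
    qc_status: str = "clean",
) -> ScoreReport:
    """Full per-case scoring: lesions -> Agatston/volume/mass/count -> bin."""
    policy = policy or SeverityPolicy()
    lesions = find_lesions(vol, roi_mask)
    ag = agatston_score(lesions)
    b, severe, unlikely = severity(ag, sex, policy)
    return ScoreReport(
        agatston=ag,
        volume_mm3=volume_score(lesions),
        mass_mg=mass_score(lesions, calibration),
        n_valid_lesions=count_valid_lesions(lesions, policy.valid_lesion_agatston),
        n_lesions=len(lesions),
        severity_bin=b,
        severe_flag=severe,
        unlikely_severe_flag=unlikely,
        qc_status=qc_status,
    )
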