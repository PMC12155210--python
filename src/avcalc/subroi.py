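"""Regional decomposition of the cylinder ROI.

The cylinder is split three ways, each into thirds:

* shells A/B/C — concentric, at radius fractions 1/3 and 2/3 of r
  (inner -> outer);
* slabs D/E/F — along the axis, thirds of the height (D = top, toward the
  aortic root; F = bottom, toward the cusps);
* sectors G/H/I — pie slices bounded by rays through the three auxiliary
  anchor points (G flanked by RAPA and PALA, H by PALA and LARA, I by LARA
  and RAPA).

Crossing the three splits yields 27 pairwise-disjoint regions covering the
ROI exactly; the 9 single-letter regions are the marginals.  Boundary voxels
go to the lower interval (upper-inclusive fractions).  Without anchors the
sector split is undefined and only the shell x slab decomposition is
produced.

Volume scores are additive across regions; the Agatston score is not when a
lesion straddles a region boundary (the per-component area/max-HU terms
change), which is logged rather than corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import CylinderParams, GeometryError, LocalFrame
from .scoring import agatston_score, find_lesions, volume_score
from .volume import ImageVolume

logger = logging.getLogger(__name__)

__all__ = [
    "SubRoiScheme",
    "RegionPartition",
    "RegionalReport",
    "sector_boundaries",
    "partition",
    "regional_scores",
    "cohort_heatmap",
]

SHELL_LABELS = ("A", "B", "C")
SLAB_LABELS = ("D", "E", "F")
SECTOR_LABELS = ("G", "H", "I")


@dataclass
class SubRoiScheme:
    """Fractional split of a cylinder into shells, slabs and sectors."""

    shell_fractions: tuple[float, ...] = (1 / 3, 2 / 3, 1.0)
    slab_fractions: tuple[float, ...] = (1 / 3, 2 / 3, 1.0)
    sector_mode: str = "anchor_rays"  # or "bisector"

    def __post_init__(self) -> None:
        for fr in (self.shell_fractions, self.slab_fractions):
            if any(b <= a for a, b in zip(fr, fr[1:])) or abs(fr[-1] - 1.0) > 1e-12:
                raise ValueError("fractions must be strictly increasing and end at 1")
        if self.sector_mode not in ("anchor_rays", "bisector"):
            raise ValueError("sector_mode must be 'anchor_rays' or 'bisector'")


def sector_boundaries(
    anchors: dict[str, np.ndarray],
    frame: LocalFrame,
    spacing: tuple[float, float, float],
    axis_origin_mm: np.ndarray | None = None,
    mode: str = "anchor_rays",
) -> dict[str, tuple[float, float]]:
    """Angular sector intervals from the three anchor points.

    Each anchor (a voxel index) is projected into the disk plane about the
    cylinder axis; boundary rays pass through the projected anchors (or, in
    "bisector" mode, midway between consecutive anchors).  Returns
    ``{label: (start_angle, end_angle)}`` with half-open CCW intervals in
    [0, 2pi); each sector's label is determined by its flanking anchor pair.
    """
    names = ("PALA", "LARA", "RAPA")
    if set(anchors) != set(names):
        raise GeometryError(f"anchors must be exactly {names}, got {sorted(anchors)}")
    sp = np.asarray(spacing, dtype=float)
    origin = frame.centroid_mm if axis_origin_mm is None else np.asarray(axis_origin_mm)
    ang = {}
    for k in names:
        p = np.asarray(anchors[k], dtype=float) * sp - origin
        x, y = float(p @ frame.pc1), float(p @ frame.pc2)
        if x * x + y * y < 1e-12:
            raise GeometryError(f"anchor {k} projects onto the cylinder axis")
        ang[k] = float(np.mod(np.arctan2(y, x), 2 * np.pi))
    vals = np.array([ang[k] for k in names])
    if np.min(np.abs(np.subtract.outer(vals, vals))[~np.eye(3, dtype=bool)]) < 1e-9:
        raise GeometryError("two anchors project to the same angle; sectors undefined")

    order = sorted(names, key=lambda k: ang[k])  # CCW circular order
    pair_label = {
        frozenset(("RAPA", "PALA")): "G",
        frozenset(("PALA", "LARA")): "H",
        frozenset(("LARA", "RAPA")): "I",
    }
    out: dict[str, tuple[float, float]] = {}
    if mode == "anchor_rays":
        for i in range(3):
            a, b = order[i], order[(i + 1) % 3]
            out[pair_label[frozenset((a, b))]] = (ang[a], ang[b])
    else:  # bisector: each sector is centered on one anchor
        for i in range(3):
            prev, a, nxt = order[(i - 1) % 3], order[i], order[(i + 1) % 3]
            out[_anchor_sector_label(a)] = (
                _circular_mid(ang[prev], ang[a]),
                _circular_mid(ang[a], ang[nxt]),
            )
    return out


def _circular_mid(a: float, b: float) -> float:
    """Midpoint of the CCW arc from a to b."""
    span = np.mod(b - a, 2 * np.pi)
    return float(np.mod(a + span / 2.0, 2 * np.pi))


def _anchor_sector_label(anchor: str) -> str:
    # In bisector mode the sector is centered on one anchor; label by the
    # flanking convention's nearest match (anchor-centered sector keeps the
    # letter of the interval it replaces most closely): PALA->G/H boundary,
    # choose the conventional mapping PALA->H, LARA->I, RAPA->G.
    return {"PALA": "H", "LARA": "I", "RAPA": "G"}[anchor]


@dataclass
class RegionPartition:
    """Per-voxel (shell, slab, sector) assignment of an ROI mask."""

    mask: np.ndarray
    shell_idx: np.ndarray  # int8 labels over the grid, -1 outside ROI
    slab_idx: np.ndarray
    sector_idx: np.ndarray | None  # None when sectors are undefined

    @property
    def has_sectors(self) -> bool:
        return self.sector_idx is not None

    def crossed_labels(self) -> list[str]:
        if self.has_sectors:
            return [
                f"{s}-{l}-{c}" for s in SHELL_LABELS for l in SLAB_LABELS for c in SECTOR_LABELS
            ]
        return [f"{s}-{l}" for s in SHELL_LABELS for l in SLAB_LABELS]

    def crossed_mask(self, label: str) -> np.ndarray:
        parts = label.split("-")
        m = (self.shell_idx == SHELL_LABELS.index(parts[0])) & (
            self.slab_idx == SLAB_LABELS.index(parts[1])
        )
        if len(parts) == 3:
            if not self.has_sectors:
                raise GeometryError("no sector decomposition available")
            m &= self.sector_idx == SECTOR_LABELS.index(parts[2])
        return m

    def marginal_mask(self, label: str) -> np.ndarray:
        if label in SHELL_LABELS:
            return self.shell_idx == SHELL_LABELS.index(label)
        if label in SLAB_LABELS:
            return self.slab_idx == SLAB_LABELS.index(label)
        if label in SECTOR_LABELS:
            if not self.has_sectors:
                raise GeometryError("no sector decomposition available")
            return self.sector_idx == SECTOR_LABELS.index(label)
        raise ValueError(f"unknown marginal label {label!r}")


def partition(
    mask: np.ndarray,
    params: CylinderParams,
    grid: ImageVolume,
    scheme: SubRoiScheme | None = None,
    sectors: dict[str, tuple[float, float]] | None = None,
    frame_pc1: np.ndarray | None = None,
) -> RegionPartition:
    """Assign every ROI voxel to exactly one (shell, slab[, sector]) triple.

    Fractions are computed from the cylinder parameters: radius fraction
    rho / r, height fraction measured downward from the top face, and the
    in-plane angle about the axis (sector intervals from
    :func:`sector_boundaries`, referenced to `frame_pc1`).  Boundary values
    fall in the lower interval.
    """
    scheme = scheme or SubRoiScheme()
    shell_idx = np.full(mask.shape, -1, dtype=np.int8)
    slab_idx = np.full(mask.shape, -1, dtype=np.int8)
    sector_idx = np.full(mask.shape, -1, dtype=np.int8) if sectors is not None else None

    idx = np.argwhere(mask)
    if idx.shape[0] == 0:
        return RegionPartition(mask, shell_idx, slab_idx, sector_idx)

    pts = grid.index_to_mm(idx.astype(float)) - params.origin_mm
    n = params.normal
    z = pts @ n
    radial = pts - np.outer(z, n)
    rho = np.linalg.norm(radial, axis=1)

    # upper-inclusive thirds: value exactly on a boundary -> lower region
    rfrac = rho / params.radius_mm
    shells = np.searchsorted(np.asarray(scheme.shell_fractions)[:-1], rfrac, side="left")
    hfrac = (params.above_mm - z) / params.height_mm  # 0 at top face, 1 at bottom
    slabs = np.searchsorted(np.asarray(scheme.slab_fractions)[:-1], hfrac, side="left")
    shells = np.clip(shells, 0, 2)
    slabs = np.clip(slabs, 0, 2)
    shell_idx[tuple(idx.T)] = shells.astype(np.int8)
    slab_idx[tuple(idx.T)] = slabs.astype(np.int8)

    if sectors is not None:
        if frame_pc1 is None:
            # any in-plane reference axis consistent with the sector angles
            raise GeometryError("frame_pc1 required when sector intervals are given")
        pc1 = np.asarray(frame_pc1, dtype=float)
        pc2 = np.cross(n, pc1)
        theta = np.mod(np.arctan2(radial @ pc2, radial @ pc1), 2 * np.pi)
        sec = np.full(idx.shape[0], -1, dtype=np.int8)
        for k, (a, b) in sectors.items():
            span = np.mod(b - a, 2 * np.pi)
            rel = np.mod(theta - a, 2 * np.pi)
            inside = rel < span if span > 1e-12 else np.zeros_like(rel, bool)
            sec[inside] = SECTOR_LABELS.index(k)
        # on-axis voxels (rho == 0) have undefined angle: assign to first sector
        sec[sec < 0] = SECTOR_LABELS.index(sorted(sectors)[0])
        sector_idx[tuple(idx.T)] = sec

    return RegionPartition(mask, shell_idx, slab_idx, sector_idx)


@dataclass
class RegionalReport:
    """Per-region Agatston and volume scores (crossed + marginal)."""

    crossed: dict[str, dict[str, float]]
    marginal: dict[str, dict[str, float]]

    def to_frame(self) -> pd.DataFrame:
        """One-row table keyed by crossed-region label ('A-D-G' style)."""
        return pd.DataFrame({k: [v["agatston"]] for k, v in self.crossed.items()})


def regional_scores(vol: ImageVolume, part: RegionPartition) -> RegionalReport:
    """Agatston and volume score per region (lesion detection re-run within
    each region mask, so per-component areas and max-HU are region-local)."""
    total_ag = agatston_score(find_lesions(vol, part.mask))

    def _score(m: np.ndarray) -> dict[str, float]:
        lesions = find_lesions(vol, m)
        return {"agatston": agatston_score(lesions), "volume_mm3": volume_score(lesions)}

    crossed = {lab: _score(part.crossed_mask(lab)) for lab in part.crossed_labels()}
    marg_labels = list(SHELL_LABELS + SLAB_LABELS) + (
        list(SECTOR_LABELS) if part.has_sectors else []
    )
    marginal = {lab: _score(part.marginal_mask(lab)) for lab in marg_labels}

    ag_sum = sum(v["agatston"] for v in crossed.values())
    if abs(ag_sum - total_ag) > 1e-6:
        logger.info(
            "Agatston not additive across regions (lesions straddle boundaries): "
            "sum %.2f vs total %.2f",
            ag_sum,
            total_ag,
        )
    return RegionalReport(crossed=crossed, marginal=marginal)


def cohort_heatmap(reports: list[RegionalReport]) -> pd.DataFrame:
    """Cohort-mean Agatston per crossed region, one column per region."""
    frames = [r.to_frame() for r in reports]
    return pd.concat(frames, ignore_index=True).mean().to_frame().T


def render_heatmap(table: pd.DataFrame, path: str) -> None:
    """Render a shells x slabs (x sectors) heatmap grid to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = list(table.columns)
    has_sectors = len(cols[0].split("-")) == 3
    sectors = SECTOR_LABELS if has_sectors else ("",)
    fig, axes = plt.subplots(1, len(sectors), figsize=(4 * len(sectors), 3.2), squeeze=False)
    vmax = max(float(table[c].iloc[0]) for c in cols) or 1.0
    for si, sec in enumerate(sectors):
        m = np.zeros((3, 3))
        for i, sl in enumerate(SLAB_LABELS):
            for j, sh in enumerate(SHELL_LABELS):
                key = f"{sh}-{sl}-{sec}" if has_sectors else f"{sh}-{sl}"
                m[i, j] = float(table[key].iloc[0])
        ax = axes[0][si]
        im = ax.imshow(m, cmap="inferno", vmin=0, vmax=vmax)
        ax.set_xticks(range(3), SHELL_LABELS)
        ax.set_yticks(range(3), SLAB_LABELS)
        ax.set_title(f"sector {sec}" if sec else "shell x slab")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
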