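"""Parameterized cylindrical valve ROI geometry.

The aortic valve region is modelled as an oblique cylinder derived from an
expert disk-like annotation: a PCA local frame is fitted to the annotated disk
voxels (in mm space), the disk is expanded radially by ``Δr`` and axially by
``dA`` (above the centroid, toward the aortic root) and ``dB`` (below, toward
the ventricle), and the resulting cylinder is fully described by eight
parameters — unit normal (μx, μy, μz), origin (x0, y0, z0), radius r and
height h = dA + dB.

Membership of a voxel (evaluated at its center, in mm) uses strict
inequalities::

    x'^2 + y'^2 < r^2        (radial)
    -dB < z' < dA            (axial)

where (x', y', z') are local-frame coordinates with z' along the normal.
"A bove" (the dA side) is the scanner-superior direction: fitted normals are
sign-fixed so that ``pc3 . (0,0,1) >= 0``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .volume import ImageVolume, grid_coords_mm

logger = logging.getLogger(__name__)

__all__ = [
    "DiskAnnotation",
    "LocalFrame",
    "ExpansionConfig",
    "CylinderParams",
    "GridCrop",
    "GeometryError",
    "fit_local_frame",
    "disk_radius",
    "expand_disk_to_cylinder",
    "reconstruct_cylinder_mask",
    "cylinder_origin_from_mask",
    "parameterize_cylinder_mask",
    "map_params_between_spaces",
]


class GeometryError(ValueError):
    """Degenerate or inconsistent geometric input."""


@dataclass
class DiskAnnotation:
    """Expert disk-like valve label: disk voxels, a center point and the three
    auxiliary anchor points (PALA, LARA, RAPA) placed between the pulmonary
    artery / left atrium / right atrium."""

    disk_voxels: np.ndarray  # (n, 3) int voxel indices
    center_point: np.ndarray  # (3,) voxel index
    anchors: dict[str, np.ndarray] = field(default_factory=dict)  # PALA/LARA/RAPA

    def __post_init__(self) -> None:
        self.disk_voxels = np.atleast_2d(np.asarray(self.disk_voxels))
        self.center_point = np.asarray(self.center_point, dtype=float)
        if self.disk_voxels.size == 0:
            raise GeometryError("disk annotation has no voxels")
        if self.anchors:
            pts = [tuple(np.asarray(v, float)) for v in self.anchors.values()]
            if len(set(pts)) != len(pts):
                raise GeometryError("anchor points must be distinct")


@dataclass
class LocalFrame:
    """Orthonormal PCA frame of the annotated disk (directions in mm space).

    pc1/pc2 span the disk plane (max variance), pc3 is the disk normal
    (least variance), sign-fixed toward scanner superior.
    """

    pc1: np.ndarray
    pc2: np.ndarray
    pc3: np.ndarray
    centroid_mm: np.ndarray

    def __post_init__(self) -> None:
        for v in (self.pc1, self.pc2, self.pc3):
            if abs(np.linalg.norm(v) - 1.0) > 1e-8:
                raise GeometryError("frame vectors must be unit length")
        for a, b in ((self.pc1, self.pc2), (self.pc1, self.pc3), (self.pc2, self.pc3)):
            if abs(float(np.dot(a, b))) > 1e-8:
                raise GeometryError("frame vectors must be orthogonal")

    def to_local(self, pos_mm: np.ndarray) -> np.ndarray:
        """Map mm positions (..., 3) to local (x', y', z') about the centroid."""
        d = np.asarray(pos_mm, dtype=float) - self.centroid_mm
        return np.stack([d @ self.pc1, d @ self.pc2, d @ self.pc3], axis=-1)


@dataclass
class ExpansionConfig:
    """Disk-to-cylinder expansion distances (mm): radial margin Δr and the
    axial extents above (dA) / below (dB) the disk centroid."""

    delta_r_mm: float = 2.0
    dA_mm: float = 10.0
    dB_mm: float = 30.0

    def __post_init__(self) -> None:
        if self.delta_r_mm < 0 or self.dA_mm < 0 or self.dB_mm < 0:
            raise ValueError("expansion distances must be non-negative")
        if self.dA_mm + self.dB_mm <= 0:
            raise ValueError("cylinder height dA + dB must be positive")


@dataclass
class CylinderParams:
    """The 8-parameter valve ROI: unit normal, origin (mm), radius, height.

    The optional dA/dB split locates the origin along the axis (dA above,
    dB below, dA + dB = h); without it the origin is at mid-height, which is
    where the center of mass of an ideal cylinder lies.
    """

    normal: np.ndarray
    origin_mm: np.ndarray
    radius_mm: float
    height_mm: float
    dA_mm: float | None = None
    dB_mm: float | None = None
    space: str = "acquisition"

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        n = float(np.linalg.norm(self.normal))
        if abs(n - 1.0) > 1e-3:
            raise GeometryError(f"normal must be unit length (|n| = {n:.6f})")
        self.normal = self.normal / n
        if self.radius_mm <= 0:
            raise GeometryError("radius must be positive")
        if self.height_mm <= 0:
            raise GeometryError("height must be positive")
        if (self.dA_mm is None) != (self.dB_mm is None):
            raise GeometryError("dA and dB must be given together")
        if self.dA_mm is not None:
            if abs(self.dA_mm + self.dB_mm - self.height_mm) > 1e-6:
                raise GeometryError("dA + dB must equal height")

    @property
    def above_mm(self) -> float:
        """Extent above the origin along the normal (dA, default h/2)."""
        return self.height_mm / 2.0 if self.dA_mm is None else self.dA_mm

    @property
    def below_mm(self) -> float:
        return self.height_mm / 2.0 if self.dB_mm is None else self.dB_mm

    def to_json(self) -> str:
        return json.dumps(
            {
                "normal": self.normal.tolist(),
                "origin_mm": self.origin_mm.tolist(),
                "radius_mm": float(self.radius_mm),
                "height_mm": float(self.height_mm),
                "dA_mm": None if self.dA_mm is None else float(self.dA_mm),
                "dB_mm": None if self.dB_mm is None else float(self.dB_mm),
                "space": self.space,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "CylinderParams":
        d = json.loads(s)
        return cls(
            normal=np.asarray(d["normal"]),
            origin_mm=np.asarray(d["origin_mm"]),
            radius_mm=d["radius_mm"],
            height_mm=d["height_mm"],
            dA_mm=d.get("dA_mm"),
            dB_mm=d.get("dB_mm"),
            space=d.get("space", "acquisition"),
        )


@dataclass
class GridCrop:
    """Geometry linking acquisition space to the isotropic crop window.

    The isotropic grid shares the acquisition origin (voxel (0,0,0) centers
    coincide) and has `iso_spacing_mm` pitch; the crop is an axis-aligned
    window of `crop_shape` iso voxels starting at `crop_offset` (may be
    negative when the window over-reaches the volume and is padded).
    """

    crop_offset: tuple[int, int, int]
    crop_shape: tuple[int, int, int]
    orig_shape: tuple[int, int, int]
    orig_spacing: tuple[float, float, float]
    orig_origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    iso_spacing_mm: float = 1.0

    @property
    def crop_origin_mm(self) -> np.ndarray:
        """mm position (acquisition frame) of crop voxel (0,0,0) center."""
        return np.asarray(self.orig_origin_mm) + np.asarray(self.crop_offset) * self.iso_spacing_mm

    @property
    def crop_extent_mm(self) -> np.ndarray:
        return np.asarray(self.crop_shape, dtype=float) * self.iso_spacing_mm


# ---------------------------------------------------------------------------
# frame fitting


def fit_local_frame(disk: DiskAnnotation, spacing: tuple[float, float, float]) -> LocalFrame:
    """Fit the PCA frame of the disk voxels, rescaled to mm.

    pc1/pc2/pc3 are the principal directions by decreasing variance; pc3 (the
    disk normal) is sign-fixed so that its scanner-superior (+z) component is
    non-negative, and pc2 = pc3 x pc1 so the frame is right-handed.
    """
    coords = disk.disk_voxels.astype(float) * np.asarray(spacing, dtype=float)
    if coords.shape[0] < 4:
        raise GeometryError("need at least 4 disk voxels to fit a frame")
    centroid = coords.mean(axis=0)
    cov = np.cov((coords - centroid).T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[1] <= max(evals[2] * 1e-10, 1e-12):
        raise GeometryError("disk voxels are collinear or coincident; cannot fit a plane")
    pc1 = evecs[:, 2]
    pc3 = evecs[:, 0]
    if pc3[2] < 0 or (pc3[2] == 0 and (pc3[0] < 0 or (pc3[0] == 0 and pc3[1] < 0))):
        pc3 = -pc3
    pc2 = np.cross(pc3, pc1)
    pc2 /= np.linalg.norm(pc2)
    pc1 = np.cross(pc2, pc3)
    pc1 /= np.linalg.norm(pc1)
    return LocalFrame(pc1=pc1, pc2=pc2, pc3=pc3, centroid_mm=centroid)


def disk_radius(
    disk: DiskAnnotation, frame: LocalFrame, spacing: tuple[float, float, float]
) -> float:
    """Largest in-plane distance from the annotated valve center to any disk
    voxel, in mm.  Distances are measured in the disk plane (x', y') from the
    projection of the annotated center point."""
    sp = np.asarray(spacing, dtype=float)
    pts = frame.to_local(disk.disk_voxels.astype(float) * sp)
    ctr = frame.to_local(disk.center_point * sp)
    d = pts[:, :2] - ctr[:2]
    return float(np.sqrt((d**2).sum(axis=1)).max())


# ---------------------------------------------------------------------------
# voxelization


def _cylinder_bbox_index(
    grid: ImageVolume,
    origin_mm: np.ndarray,
    normal: np.ndarray,
    radius: float,
    above: float,
    below: float,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Index bounds (lo, hi half-open) of the cylinder's mm bounding box,
    clipped to the grid; also whether clipping occurred."""
    n = np.asarray(normal, dtype=float)
    perp = radius * np.sqrt(np.clip(1.0 - n**2, 0.0, 1.0))
    top = origin_mm + above * n
    bot = origin_mm - below * n
    lo_mm = np.minimum(top, bot) - perp
    hi_mm = np.maximum(top, bot) + perp
    lo = np.floor(grid.mm_to_index(lo_mm)).astype(int)
    hi = np.ceil(grid.mm_to_index(hi_mm)).astype(int) + 1
    clipped = bool(np.any(lo < 0) or np.any(hi > np.asarray(grid.shape)))
    lo_c = np.clip(lo, 0, grid.shape)
    hi_c = np.clip(hi, 0, grid.shape)
    return lo_c, hi_c, clipped


def _voxelize(
    grid: ImageVolume,
    origin_mm: np.ndarray,
    normal: np.ndarray,
    radius: float,
    above: float,
    below: float,
    what: str,
) -> np.ndarray:
    """Strict-inequality cylinder membership of voxel centers (vectorized)."""
    mask = np.zeros(grid.shape, dtype=bool)
    lo, hi, clipped = _cylinder_bbox_index(grid, origin_mm, normal, radius, above, below)
    if clipped:
        logger.warning(
            "%s: cylinder extends outside the grid (shape %s); mask clipped", what, grid.shape
        )
    if np.any(hi <= lo):
        return mask
    xs, ys, zs = grid_coords_mm(grid.shape, grid.spacing, grid.origin_mm, tuple(lo), tuple(hi))
    dx = xs - origin_mm[0]
    dy = ys - origin_mm[1]
    dz = zs - origin_mm[2]
    zp = (
        dx[:, None, None] * normal[0]
        + dy[None, :, None] * normal[1]
        + dz[None, None, :] * normal[2]
    )
    r2 = (
        dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
    ) - zp**2
    sub = (r2 < radius**2) & (zp > -below) & (zp < above)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = sub
    return mask


def expand_disk_to_cylinder(
    disk: DiskAnnotation,
    frame: LocalFrame,
    cfg: ExpansionConfig,
    grid: ImageVolume,
) -> np.ndarray:
    """Expand the annotated disk into the cylinder ROI on the acquisition grid.

    Final radius = measured disk radius + Δr; axial extent (-dB, dA) about the
    PCA centroid along pc3.  Returns a boolean mask in the grid's native axis
    order.
    """
    r = disk_radius(disk, frame, grid.spacing) + cfg.delta_r_mm
    return _voxelize(
        grid, frame.centroid_mm, frame.pc3, r, cfg.dA_mm, cfg.dB_mm, "expand_disk_to_cylinder"
    )


def reconstruct_cylinder_mask(p: CylinderParams, grid: ImageVolume) -> np.ndarray:
    """Voxelize a parameterized cylinder on a grid (same membership rule as
    the disk expansion, expressed from the 8 parameters)."""
    if p.radius_mm < min(grid.spacing[0], grid.spacing[1]) / 2.0:
        warnings.warn("cylinder radius below half the in-plane spacing; mask is empty")
        return np.zeros(grid.shape, dtype=bool)
    return _voxelize(
        grid, p.origin_mm, p.normal, p.radius_mm, p.above_mm, p.below_mm, "reconstruct_cylinder_mask"
    )


def cylinder_origin_from_mask(mask: np.ndarray, grid: ImageVolume) -> np.ndarray:
    """Unweighted mm centroid of mask voxel centers (the cylinder origin)."""
    idx = np.argwhere(mask)
    if idx.shape[0] == 0:
        raise GeometryError("empty mask: segmentation failed, no origin")
    return grid.index_to_mm(idx.astype(float)).mean(axis=0)


def parameterize_cylinder_mask(mask: np.ndarray, grid: ImageVolume) -> CylinderParams:
    """Recover (normal, origin, r, h) from a voxelized cylinder mask.

    Origin is the center of mass; the axis is the maximal-variance principal
    direction of the voxel centers (valid while h > r*sqrt(3), true for the
    valve ROI); height from the axial second moment of a uniform cylinder
    (var(z') = h^2/12); radius by matching the voxelized volume to pi r^2 h.
    """
    idx = np.argwhere(mask)
    if idx.shape[0] < 8:
        raise GeometryError("mask too small to parameterize")
    pts = grid.index_to_mm(idx.astype(float))
    origin = pts.mean(axis=0)
    cov = np.cov((pts - origin).T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, 2]
    if axis[2] < 0:
        axis = -axis
    # refine the axis: slab centroids of an ideal cylinder lie on the axis,
    # so a line fit through them is far less sensitive to the shrinking
    # eigen-gap at large radii than raw PCA
    for _ in range(3):
        z = (pts - origin) @ axis
        span = z.max() - z.min()
        # interior slabs only: end caps cut the slab regions asymmetrically
        # and would bias the centroids off the axis
        edges = np.linspace(z.min() + 0.15 * span, z.max() - 0.15 * span, 9)
        centers = []
        weights = []
        for a, b in zip(edges[:-1], edges[1:]):
            sel = (z >= a) & (z < b)
            if sel.sum() < 4:
                continue
            centers.append(pts[sel].mean(axis=0))
            weights.append(sel.sum())
        if len(centers) < 3:
            break
        C = np.asarray(centers)
        w = np.asarray(weights, dtype=float)
        C = C - (C * w[:, None]).sum(axis=0) / w.sum()
        cc = (C * w[:, None]).T @ C
        new_axis = np.linalg.eigh(cc)[1][:, 2]
        if new_axis[2] < 0:
            new_axis = -new_axis
        axis = new_axis
    z = (pts - origin) @ axis
    h = float(np.sqrt(12.0 * z.var()))
    vol = idx.shape[0] * grid.voxel_volume_mm3
    r = float(np.sqrt(vol / (np.pi * h)))
    return CylinderParams(normal=axis, origin_mm=origin, radius_mm=r, height_mm=h)


# ---------------------------------------------------------------------------
# space mapping


def map_params_between_spaces(
    p: CylinderParams, crop: GridCrop, direction: str
) -> CylinderParams:
    """Map cylinder parameters acquisition <-> isotropic-crop space.

    Both spaces are axis-aligned and in mm, so direction vectors, radius and
    height are invariant; only the origin is translated by the crop offset.
    """
    shift = crop.crop_origin_mm
    if direction == "to_crop":
        if p.space != "acquisition":
            raise ValueError(f"expected acquisition-space params, got {p.space!r}")
        new_origin = p.origin_mm - shift
        new_space = "iso_crop"
    elif direction == "to_acquisition":
        if p.space != "iso_crop":
            raise ValueError(f"expected iso_crop-space params, got {p.space!r}")
        new_origin = p.origin_mm + shift
        new_space = "acquisition"
        idx = (new_origin - np.asarray(crop.orig_origin_mm)) / np.asarray(crop.orig_spacing)
        if np.any(idx < -0.5) or np.any(idx > np.asarray(crop.orig_shape) - 0.5):
            raise GeometryError(
                f"cylinder center {new_origin} lies outside the original field of view"
            )
    else:
        raise ValueError("direction must be 'to_crop' or 'to_acquisition'")
    return CylinderParams(
        normal=p.normal.copy(),
        origin_mm=new_origin,
        radius_mm=p.radius_mm,
        height_mm=p.height_mm,
        dA_mm=p.dA_mm,
        dB_mm=p.dB_mm,
        space=new_space,
    )
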