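"""Synthetic CT calcium-score phantoms with known valve-cylinder truth.

A phantom is an abstract non-contrast cardiac CT look-alike: a soft-tissue
background with smooth shading, a heart-like ellipsoid, an ascending-aorta
tube whose lower end marks the valve plane (the anatomy cue a model can learn
localization from), a descending-aorta tube for noise QC, calcific blobs
rendered as clipped Gaussians (smooth, partial-volume-like edges so the
>= 130 HU / >= 1 mm^2 criteria are exercised non-trivially), optional
Gaussian noise and 1-voxel streak artifacts.  No projection/reconstruction
physics is modelled — the goal is exact geometric/statistical ground truth,
not visual realism.

Every phantom carries its generating cylinder parameters, masks, and an
expected score report computed from the rendered image by the scoring module,
so downstream modules can be validated end to end.  Generation is
deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    CylinderParams,
    DiskAnnotation,
    reconstruct_cylinder_mask,
)
from .scoring import ScoreReport, score_roi
from .volume import ImageVolume

__all__ = [
    "CalcBlob",
    "PhantomSpec",
    "PhantomTruth",
    "generate",
    "add_streaks",
    "make_cohort",
    "random_cylinder",
]

# default acquisition-like grid: anisotropic, like a coned-down calcium scan
DEFAULT_SHAPE = (96, 96, 26)
DEFAULT_SPACING = (0.7, 0.7, 2.5)

# background / anatomy HU levels (all well under the 130 HU calcium threshold)
HU_TISSUE = 35.0
HU_HEART = 48.0
HU_BLOOD = 60.0
HU_AORTA_WALL = 100.0
HU_DESC_AORTA = 45.0

# the valve plane lies above the cylinder's center of mass: the ROI spans
# dA = 10 mm above the plane and dB = 30 mm below it, so plane = CoM + 10 n
PLANE_OFFSET_MM = 10.0


@dataclass
class CalcBlob:
    """One calcific deposit: a clipped-Gaussian HU bump."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    peak_hu: float
    inside: bool = True  # inside the valve cylinder vs coronary-like distractor
    region_hint: str = ""  # optional target sub-region label

    def __post_init__(self) -> None:
        if not (130.0 <= self.peak_hu <= 1000.0):
            raise ValueError("blob peak HU must lie in [130, 1000]")
        if self.radius_mm <= 0:
            raise ValueError("blob radius must be positive")


@dataclass
class PhantomSpec:
    """Full description of one phantom; rendering is a pure function of it."""

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    cylinder: CylinderParams | None = None  # default: random from seed
    blobs: list[CalcBlob] = field(default_factory=list)
    noise_sigma_hu: float = 5.0
    streak_count: int = 0
    streak_amplitude_hu: float = 0.0
    sex: str = "unknown"
    seed: int = 0


@dataclass
class PhantomTruth:
    """A rendered phantom plus everything needed to validate the pipeline."""

    spec: PhantomSpec
    image: ImageVolume
    cylinder_mask: np.ndarray
    params: CylinderParams
    disk: DiskAnnotation
    calc_mask: np.ndarray
    aorta_mask: np.ndarray
    heart_bounds_mm: np.ndarray
    expected_report: ScoreReport
    sex: str = "unknown"


def random_cylinder(
    rng: np.random.Generator,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    radius_range: tuple[float, float] = (16.0, 22.0),
    max_tilt_deg: float = 12.0,
    jitter_mm: float = 5.0,
) -> CylinderParams:
    """Sample a valve-like cylinder: r in the cohort range, h = 40 mm
    (dA = 10 above / dB = 30 below the valve plane... expressed about the
    center of mass, i.e. symmetric split), mild tilt from superior."""
    extent = np.asarray(shape) * np.asarray(spacing)
    r = float(rng.uniform(*radius_range))
    tilt = np.deg2rad(rng.uniform(0.0, max_tilt_deg))
    phi = rng.uniform(0.0, 2 * np.pi)
    normal = np.array(
        [np.sin(tilt) * np.cos(phi), np.sin(tilt) * np.sin(phi), np.cos(tilt)]
    )
    jit = np.array([jitter_mm, jitter_mm, min(jitter_mm, 2.0)])
    center = extent / 2.0 + rng.uniform(-jit, jit)
    return CylinderParams(normal=normal, origin_mm=center, radius_mm=r, height_mm=40.0)


def _local_coords(grid: ImageVolume, p: CylinderParams):
    """(z', rho) cylindrical coordinates of every voxel center."""
    xs = np.asarray(grid.origin_mm)[0] + np.arange(grid.shape[0]) * grid.spacing[0]
    ys = np.asarray(grid.origin_mm)[1] + np.arange(grid.shape[1]) * grid.spacing[1]
    zs = np.asarray(grid.origin_mm)[2] + np.arange(grid.shape[2]) * grid.spacing[2]
    dx = xs[:, None, None] - p.origin_mm[0]
    dy = ys[None, :, None] - p.origin_mm[1]
    dz = zs[None, None, :] - p.origin_mm[2]
    zp = dx * p.normal[0] + dy * p.normal[1] + dz * p.normal[2]
    rho2 = dx**2 + dy**2 + dz**2 - zp**2
    return zp, np.sqrt(np.maximum(rho2, 0.0))


def _dist2_mm(grid: ImageVolume, center: np.ndarray):
    xs = np.asarray(grid.origin_mm)[0] + np.arange(grid.shape[0]) * grid.spacing[0]
    ys = np.asarray(grid.origin_mm)[1] + np.arange(grid.shape[1]) * grid.spacing[1]
    zs = np.asarray(grid.origin_mm)[2] + np.arange(grid.shape[2]) * grid.spacing[2]
    return (
        (xs[:, None, None] - center[0]) ** 2
        + (ys[None, :, None] - center[1]) ** 2
        + (zs[None, None, :] - center[2]) ** 2
    )


def _render_structure(grid: ImageVolume, p: CylinderParams, seed: int) -> np.ndarray:
    """Anatomy-like background (everything except calcium, noise, streaks)."""
    from scipy import ndimage

    rng = np.random.default_rng([seed, 11])
    img = np.full(grid.shape, HU_TISSUE, dtype=np.float32)
    # smooth shading so the background is not constant
    shade = ndimage.gaussian_filter(rng.normal(0.0, 1.0, grid.shape), sigma=4.0)
    img += (6.0 * shade / max(shade.std(), 1e-6)).astype(np.float32)

    zp, rho = _local_coords(grid, p)
    extent = np.asarray(grid.shape) * np.asarray(grid.spacing)
    zv = zp - PLANE_OFFSET_MM  # height above the valve plane

    # heart sac: ellipsoid around the cylinder center of mass
    d2 = _dist2_mm(grid, p.origin_mm)
    heart = d2 < 34.0**2
    img[heart] = HU_HEART

    # ventricular blood pool below the valve plane
    lv = (d2 < 26.0**2) & (zv < -4.0)
    img[lv] = HU_BLOOD - 5.0

    # ascending aorta: tube along the cylinder axis above the valve plane,
    # lumen + bright wall; its caliber tracks the valve radius, which is the
    # visual cue for radius regression
    r_lumen = p.radius_mm - 6.0
    tube = (zv > -2.0) & (zv < 26.0)
    img[tube & (rho < r_lumen)] = HU_BLOOD
    img[tube & (rho >= r_lumen) & (rho < r_lumen + 2.5)] = HU_AORTA_WALL

    # annulus ring at the valve plane (dense tissue, still sub-threshold)
    ring = (np.abs(zv) < 2.0) & (rho > p.radius_mm - 6.0) & (rho < p.radius_mm - 2.0)
    img[ring] = 110.0

    # descending aorta: straight z tube in a fixed corner, used for noise QC
    desc_c = np.array([0.18 * extent[0], 0.8 * extent[1]])
    xs = np.asarray(grid.origin_mm)[0] + np.arange(grid.shape[0]) * grid.spacing[0]
    ys = np.asarray(grid.origin_mm)[1] + np.arange(grid.shape[1]) * grid.spacing[1]
    desc = (
        (xs[:, None, None] - desc_c[0]) ** 2 + (ys[None, :, None] - desc_c[1]) ** 2
    ) < 6.0**2
    img[np.broadcast_to(desc, grid.shape)] = HU_DESC_AORTA
    return img


def _desc_aorta_mask(grid: ImageVolume) -> np.ndarray:
    extent = np.asarray(grid.shape) * np.asarray(grid.spacing)
    desc_c = np.array([0.18 * extent[0], 0.8 * extent[1]])
    xs = np.asarray(grid.origin_mm)[0] + np.arange(grid.shape[0]) * grid.spacing[0]
    ys = np.asarray(grid.origin_mm)[1] + np.arange(grid.shape[1]) * grid.spacing[1]
    desc = (
        (xs[:, None, None] - desc_c[0]) ** 2 + (ys[None, :, None] - desc_c[1]) ** 2
    ) < 6.0**2
    return np.broadcast_to(desc, grid.shape).copy()


def _render_blobs(grid: ImageVolume, blobs: list[CalcBlob]) -> np.ndarray:
    """Additive clipped-Gaussian HU bumps."""
    out = np.zeros(grid.shape, dtype=np.float32)
    for b in blobs:
        c = np.asarray(b.center_mm, dtype=float)
        idx = (c - np.asarray(grid.origin_mm)) / np.asarray(grid.spacing)
        if np.any(idx < 0) or np.any(idx > np.asarray(grid.shape) - 1):
            raise ValueError(f"blob at {b.center_mm} lies outside the grid")
        d2 = _dist2_mm(grid, c)
        sigma = b.radius_mm / 1.5
        bump = b.peak_hu * np.exp(-d2 / (2.0 * sigma**2))
        out += np.minimum(bump, b.peak_hu).astype(np.float32)
    return out


def _blob_inside_ok(b: CalcBlob, p: CylinderParams) -> bool:
    v = np.asarray(b.center_mm) - p.origin_mm
    z = float(v @ p.normal)
    rho = float(np.sqrt(max((v @ v) - z * z, 0.0)))
    return rho < p.radius_mm and -p.below_mm < z < p.above_mm


def _blob_outside_safe(b: CalcBlob, p: CylinderParams, margin: float = 3.0) -> bool:
    """Distractor blob far enough that its >=130 HU core cannot touch the ROI."""
    v = np.asarray(b.center_mm) - p.origin_mm
    z = float(v @ p.normal)
    rho = float(np.sqrt(max((v @ v) - z * z, 0.0)))
    # distance from center to the cylinder surface (outside only)
    dr = max(rho - p.radius_mm, 0.0)
    dz = max(z - p.above_mm, -p.below_mm - z, 0.0)
    dist = float(np.hypot(dr, dz))
    core = b.radius_mm / 1.5 * np.sqrt(2.0 * np.log(max(b.peak_hu / 100.0, 1.01)))
    return dist > core + margin


def make_disk_annotation(
    p: CylinderParams, grid: ImageVolume, delta_r_mm: float = 2.0
) -> DiskAnnotation:
    """Synthesize the expert disk label a cardiologist would have drawn:
    voxels within one voxel of the valve plane and inside the valve radius
    (cylinder radius minus the radial margin), a center point on the axis and
    the three anchor points just outside the valve rim."""
    zp, rho = _local_coords(grid, p)
    zv = zp - PLANE_OFFSET_MM  # the disk lives in the valve plane
    # one-slice-thick slab: half the voxel pitch along the normal direction
    half = 0.51 * float(np.abs(p.normal) @ np.asarray(grid.spacing))
    disk = (np.abs(zv) <= half) & (rho < p.radius_mm - delta_r_mm)
    voxels = np.argwhere(disk)
    if voxels.shape[0] < 4:
        raise ValueError("grid too coarse to carry a disk annotation")
    center_idx = np.asarray(
        np.unravel_index(np.argmin(np.abs(zv) + rho), grid.shape), dtype=float
    )
    # in-plane basis for placing anchors
    ref = np.array([1.0, 0.0, 0.0])
    if abs(p.normal[0]) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(p.normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(p.normal, e1)
    anchors = {}
    plane_c = p.origin_mm + PLANE_OFFSET_MM * p.normal
    for name, ang in (("PALA", np.pi / 2), ("LARA", 7 * np.pi / 6), ("RAPA", 11 * np.pi / 6)):
        pos = plane_c + (p.radius_mm + 1.0) * (np.cos(ang) * e1 + np.sin(ang) * e2)
        idx = np.clip(
            np.round((pos - np.asarray(grid.origin_mm)) / np.asarray(grid.spacing)),
            0,
            np.asarray(grid.shape) - 1,
        )
        anchors[name] = idx.astype(int)
    return DiskAnnotation(disk_voxels=voxels, center_point=center_idx, anchors=anchors)


def add_streaks(
    values: np.ndarray, count: int, amplitude: float, seed: int
) -> np.ndarray:
    """Add 1-voxel-wide oriented line artifacts (photon-starvation look-alike).

    Each streak is a straight chord across one axial slice with a random
    +/- amplitude; thin alternating lines raise the sub-130-HU std statistic
    and are largely removed by a 3x3 median filter.
    """
    from skimage.draw import line as draw_line

    out = values.copy()
    if count <= 0 or amplitude == 0:
        return out
    rng = np.random.default_rng([seed, 17])
    nx, ny, nz = out.shape
    for _ in range(count):
        z = int(rng.integers(0, nz))
        if rng.random() < 0.5:
            r0, c0 = 0, int(rng.integers(0, ny))
            r1, c1 = nx - 1, int(rng.integers(0, ny))
        else:
            r0, c0 = int(rng.integers(0, nx)), 0
            r1, c1 = int(rng.integers(0, nx)), ny - 1
        rr, cc = draw_line(r0, c0, r1, c1)
        out[rr, cc, z] += amplitude * (1.0 if rng.random() < 0.5 else -1.0)
    return out


def calibrate_streak_amplitude(
    target_std_hu: float,
    seed: int,
    streak_count: int = 400,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    lo: float = 5.0,
    hi: float = 800.0,
    iters: int = 14,
) -> float:
    """Bisection sweep for the streak amplitude that drives the aorta-noise
    statistic to `target_std_hu` for this seed's streak geometry.

    The streak line pattern is a pure function of the seed, so the measured
    std is monotone in amplitude and a sweep pins the QC operating point
    regardless of how many streaks happen to cross the aorta.
    """
    from .qc import aorta_noise

    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        t = generate(replace(PhantomSpec(seed=seed, shape=shape, spacing=spacing),
                             streak_count=streak_count, streak_amplitude_hu=mid))
        std = aorta_noise(t.image, t.aorta_mask).std_hu
        if std < target_std_hu:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate(spec: PhantomSpec) -> PhantomTruth:
    """Render a phantom and its exact truth records (deterministic per seed)."""
    rng = np.random.default_rng([spec.seed, 3])
    p = spec.cylinder or random_cylinder(rng, spec.shape, spec.spacing)
    grid = ImageVolume(np.zeros(spec.shape, dtype=np.float32), spec.spacing)

    for b in spec.blobs:
        if b.inside and not _blob_inside_ok(b, p):
            raise ValueError(f"inside-flagged blob at {b.center_mm} violates the cylinder rule")
        if not b.inside and not _blob_outside_safe(b, p):
            raise ValueError(f"distractor blob at {b.center_mm} is too close to the cylinder")

    img = _render_structure(grid, p, spec.seed)
    img += _render_blobs(grid, spec.blobs)
    if spec.noise_sigma_hu > 0:
        noise_rng = np.random.default_rng([spec.seed, 13])
        img += noise_rng.normal(0.0, spec.noise_sigma_hu, grid.shape).astype(np.float32)
    if spec.streak_count > 0:
        img = add_streaks(img, spec.streak_count, spec.streak_amplitude_hu, spec.seed)

    vol = ImageVolume(img.astype(np.float32), spec.spacing)
    cyl_mask = reconstruct_cylinder_mask(p, vol)
    calc_mask = (vol.values >= 130.0) & cyl_mask
    disk = make_disk_annotation(p, vol)
    aorta = _desc_aorta_mask(vol)
    heart_bounds = np.stack([p.origin_mm - 34.0, p.origin_mm + 34.0])
    report = score_roi(vol, cyl_mask, sex=spec.sex)
    return PhantomTruth(
        spec=spec,
        image=vol,
        cylinder_mask=cyl_mask,
        params=p,
        disk=disk,
        calc_mask=calc_mask,
        aorta_mask=aorta,
        heart_bounds_mm=heart_bounds,
        expected_report=report,
        sex=spec.sex,
    )


# ---------------------------------------------------------------------------
# cohort generation

_BIN_TARGETS = {
    "0": (0.0, 0.0, 0.0),
    "1-800": (100.0, 600.0, 800.0),
    "800-1200": (850.0, 1150.0, 1200.0),
    "1200-2000": (1300.0, 1900.0, 2000.0),
    "2000+": (2100.0, 3200.0, float("inf")),
}

# blob ladder: (radius mm, peak HU, approximate Agatston on the default grid)
_BLOB_LADDER = (
    (1.5, 300.0, 15.0),
    (2.0, 400.0, 70.0),
    (2.5, 600.0, 220.0),
    (3.0, 700.0, 450.0),
    (4.0, 800.0, 1100.0),
)

DEFAULT_MIX = {"0": 0.4, "1-800": 0.3, "800-1200": 0.1, "1200-2000": 0.1, "2000+": 0.1}


def _allocate(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n cases to severity bins."""
    raw = {k: n * v for k, v in mix.items()}
    base = {k: int(np.floor(v)) for k, v in raw.items()}
    rem = n - sum(base.values())
    order = sorted(mix, key=lambda k: raw[k] - base[k], reverse=True)
    for k in order[:rem]:
        base[k] += 1
    return base


def _place_inside_blob(
    rng: np.random.Generator, p: CylinderParams, radius_mm: float
) -> np.ndarray:
    """Uniform position inside the cylinder with margin for the blob core."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(p.normal[2]) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(p.normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(p.normal, e1)
    rmax = max(p.radius_mm - radius_mm - 1.0, 1.0)
    rho = rmax * np.sqrt(rng.random())
    th = rng.uniform(0, 2 * np.pi)
    z = rng.uniform(-p.below_mm + radius_mm + 1.0, p.above_mm - radius_mm - 1.0)
    return p.origin_mm + rho * (np.cos(th) * e1 + np.sin(th) * e2) + z * p.normal


def make_cohort(
    n: int,
    seed: int,
    severity_mix: dict[str, float] | None = None,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    sexes: tuple[str, ...] = ("male", "female"),
    noise_sigma_hu: float = 2.0,
) -> list[PhantomTruth]:
    """Generate a cohort spanning the severity bins.

    Per case, calcific blobs are added (and measured with the scoring module
    on the actual rendered image) until the total Agatston score lands in the
    requested bin, so the realized bins match the request.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    mix = severity_mix or DEFAULT_MIX
    alloc = _allocate(n, mix)
    bins: list[str] = [b for b, c in alloc.items() for _ in range(c)]
    master = np.random.default_rng([seed, 101])
    master.shuffle(bins)

    out: list[PhantomTruth] = []
    for i, target_bin in enumerate(bins):
        case_seed = int(np.random.default_rng([seed, 211, i]).integers(0, 2**31 - 1))
        rng = np.random.default_rng([case_seed, 5])
        p = random_cylinder(rng, shape, spacing)
        lo, hi, top = _BIN_TARGETS[target_bin]
        target = 0.0 if hi == 0 else float(rng.uniform(lo, hi))
        spec = PhantomSpec(
            shape=shape,
            spacing=spacing,
            cylinder=p,
            blobs=[],
            noise_sigma_hu=noise_sigma_hu,
            sex=sexes[i % len(sexes)],
            seed=case_seed,
        )
        blobs: list[CalcBlob] = []
        truth = generate(spec)
        for _ in range(60):
            ag = truth.expected_report.agatston
            if ag >= target:
                break
            gap = target - ag
            # the next blob must not push the score past the bin's upper edge
            limit = gap * 1.1
            if np.isfinite(top):
                limit = min(limit, 0.6 * (top - ag))
            step = _BLOB_LADDER[0]
            for cand in _BLOB_LADDER:
                if cand[2] <= limit:
                    step = cand
            rb, peak, _ = step
            peak = float(np.clip(peak * rng.uniform(0.95, 1.05), 130.0, 1000.0))
            blobs.append(
                CalcBlob(
                    center_mm=tuple(_place_inside_blob(rng, p, rb)),
                    radius_mm=rb,
                    peak_hu=peak,
                )
            )
            truth = generate(replace(spec, blobs=list(blobs)))
        out.append(truth)
    return out
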