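"""Dataset preparation, training loop and inference for the cylinder network.

Training cases are (isotropic windowed image, cylinder label mask, 7-vector)
triples.  The reference protocol is batch 8 for 600 epochs on 176x176x128
volumes with a 65/15/20 train/val/test split and on-the-fly Gaussian-noise
augmentation (std 0.1 on the [0, 1] intensity scale); the desk preset scales
this to 64-voxel cubes and a few dozen phantoms so a full run fits on one
CPU.  At inference the cylinder origin comes from the center of mass of the
thresholded branch-1 segmentation (CoM linkage); normal and radius come from
branch-2; the height is fixed at 40 mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..geometry import (
    CylinderParams,
    GridCrop,
    map_params_between_spaces,
    reconstruct_cylinder_mask,
)
from ..qc import resample_crop, window_normalize
from ..volume import ImageVolume
from .autodiff import Tensor
from .losses import LossWeights, combined_loss
from .network import (
    FIXED_HEIGHT_MM,
    MultiTaskCylinderNet,
    NetConfig,
    build_network,
    decode_params,
    encode_params,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "CaseTensors",
    "prepare_case",
    "split_indices",
    "split_and_train",
    "predict_cylinder",
    "cylinder_metrics",
    "Adam",
]


@dataclass
class TrainConfig:
    """Optimization protocol; defaults follow the reference configuration."""

    batch_size: int = 8
    epochs: int = 600
    split_fractions: tuple[float, float, float] = (0.65, 0.15, 0.20)
    split_counts: tuple[int, int, int] | None = None  # explicit override
    augment_noise_std: float = 0.1
    learning_rate: float = 2e-3
    lr_final_factor: float = 0.1  # cosine decay floor
    grad_clip: float = 5.0  # global-norm clip
    recon_downsample: int = 2  # branch-3 grid = input shape / this
    sharpness: float = 50.0
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    @classmethod
    def desk(cls, epochs: int = 30, seed: int = 0) -> "TrainConfig":
        """Single-CPU scaled-down preset (64-cube inputs, small batches)."""
        return cls(batch_size=4, epochs=epochs, seed=seed)


@dataclass
class CaseTensors:
    """One prepared training case in the iso-crop frame."""

    image: np.ndarray  # (X, Y, Z) in [0, 1]
    label: np.ndarray  # bool cylinder mask
    pvec: np.ndarray  # (7,) encoded parameters
    crop: GridCrop
    params_crop: CylinderParams


def prepare_case(
    vol: ImageVolume,
    params_acq: CylinderParams,
    heart_bounds_mm: np.ndarray,
    out_shape: tuple[int, int, int] = (64, 64, 64),
) -> CaseTensors:
    """Window, resample-crop and encode one case for training."""
    iso, crop = resample_crop(vol, heart_bounds_mm, out_shape=out_shape)
    img = window_normalize(iso).values
    p_crop = map_params_between_spaces(params_acq, crop, "to_crop")
    crop_grid = ImageVolume(np.zeros(out_shape, dtype=np.float32), (crop.iso_spacing_mm,) * 3)
    label = reconstruct_cylinder_mask(p_crop, crop_grid)
    pvec = encode_params(p_crop.normal, p_crop.origin_mm, p_crop.radius_mm, crop.crop_extent_mm)
    return CaseTensors(image=img, label=label, pvec=pvec, crop=crop, params_crop=p_crop)


def split_indices(
    n: int, cfg: TrainConfig, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic shuffled split.  Default rounding: floor(train),
    floor(val), remainder to test; `split_counts` overrides exactly."""
    rng = np.random.default_rng([cfg.seed if seed is None else seed, 41])
    order = rng.permutation(n)
    if cfg.split_counts is not None:
        nt, nv, nh = cfg.split_counts
        if nt + nv + nh != n:
            raise ValueError("split_counts must sum to the dataset size")
    else:
        nt = int(np.floor(n * cfg.split_fractions[0]))
        nv = int(np.floor(n * cfg.split_fractions[1]))
        nh = n - nt - nv
    return order[:nt], order[nt : nt + nv], order[nt + nv :]


class Adam:
    """Adam optimizer with optional global-norm gradient clipping."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps=1e-8, grad_clip: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.grad_clip = grad_clip
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        scale = 1.0
        if self.grad_clip > 0:
            total = np.sqrt(sum(float((p.grad**2).sum()) for p in self.params if p.grad is not None))
            if total > self.grad_clip:
                scale = self.grad_clip / total
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)


def _batch_arrays(cases: list[CaseTensors], idx: np.ndarray):
    x = np.stack([cases[i].image for i in idx])[:, None].astype(np.float32)
    y = np.stack([cases[i].label for i in idx])[:, None].astype(np.float32)
    p = np.stack([cases[i].pvec for i in idx]).astype(np.float32)
    return x, y, p


def split_and_train(
    cases: list[CaseTensors],
    cfg: TrainConfig | None = None,
    net_config: NetConfig | None = None,
) -> tuple[MultiTaskCylinderNet, list[dict]]:
    """Train the three-branch network; returns (model, per-epoch metric log).

    Validation reports the reconstructed-cylinder Dice and the CoM-linkage
    origin error, the quantities that matter downstream.
    """
    cfg = cfg or TrainConfig()
    if len(cases) < cfg.batch_size:
        raise ValueError(f"dataset of {len(cases)} smaller than one batch ({cfg.batch_size})")
    in_shape = cases[0].image.shape
    net_config = net_config or NetConfig(input_shape=in_shape, seed=cfg.seed)
    net = build_network(net_config)
    tr, va, te = split_indices(len(cases), cfg)
    logger.info("split: %d train / %d val / %d test", len(tr), len(va), len(te))
    opt = Adam(net.parameters(), lr=cfg.learning_rate, grad_clip=cfg.grad_clip)
    rng = np.random.default_rng([cfg.seed, 53])
    extent = cases[0].crop.crop_extent_mm
    recon_shape = tuple(s // cfg.recon_downsample for s in in_shape)

    log: list[dict] = []
    for epoch in range(cfg.epochs):
        # cosine decay from learning_rate to learning_rate * lr_final_factor
        frac = epoch / max(cfg.epochs - 1, 1)
        floor = cfg.lr_final_factor
        opt.lr = cfg.learning_rate * (floor + (1 - floor) * 0.5 * (1 + np.cos(np.pi * frac)))
        order = rng.permutation(tr)
        ep_terms: dict[str, float] = {}
        nb = 0
        for start in range(0, len(order) - cfg.batch_size + 1, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            x, y, p = _batch_arrays(cases, idx)
            if cfg.augment_noise_std > 0:
                x = x + rng.normal(0, cfg.augment_noise_std, x.shape).astype(np.float32)
            xt = Tensor(x)
            logits, pvec = net.forward(xt, training=True)
            loss, terms = combined_loss(
                logits,
                y,
                pvec,
                p,
                cfg.weights,
                recon_grid_shape=recon_shape,
                extent_mm=extent,
                sharpness=cfg.sharpness,
            )
            opt.zero_grad()
            loss.backward()
            opt.step()
            for k, v in terms.items():
                ep_terms[k] = ep_terms.get(k, 0.0) + v
            nb += 1
        entry = {"epoch": epoch, **{k: v / max(nb, 1) for k, v in ep_terms.items()}}
        if len(va) and (epoch % 5 == 4 or epoch == cfg.epochs - 1):
            entry.update(evaluate(net, cases, va))
        log.append(entry)
        logger.info("epoch %d: %s", epoch, {k: round(v, 4) for k, v in entry.items() if k != "epoch"})
    return net, log


def evaluate(
    net: MultiTaskCylinderNet, cases: list[CaseTensors], idx: np.ndarray
) -> dict[str, float]:
    """Mean validation metrics: recon Dice, origin error, radius error,
    normal cosine similarity, plus branch-1 mask Dice."""
    dices, recon_dices, origin_errs, radius_errs, cossims = [], [], [], [], []
    for i in idx:
        c = cases[i]
        pred, _ = predict_cylinder_crop(net, c.image, c.crop)
        grid = ImageVolume(
            np.zeros(c.image.shape, dtype=np.float32), (c.crop.iso_spacing_mm,) * 3
        )
        m = cylinder_metrics(pred, c.params_crop, grid)
        recon_dices.append(m["dice"])
        origin_errs.append(m["origin_dist_mm"])
        radius_errs.append(m["radius_abs_diff_mm"])
        cossims.append(m["normal_cos_sim"])
        logits, _ = net.forward(c.image[None, None].astype(np.float32))
        seg = logits.sigmoid().data[0, 0] >= 0.5
        inter = float(np.logical_and(seg, c.label).sum())
        dices.append(2 * inter / max(float(seg.sum() + c.label.sum()), 1.0))
    return {
        "val_mask_dice": float(np.mean(dices)),
        "val_recon_dice": float(np.mean(recon_dices)),
        "val_origin_err_mm": float(np.mean(origin_errs)),
        "val_radius_err_mm": float(np.mean(radius_errs)),
        "val_normal_cos": float(np.mean(cossims)),
    }


def predict_cylinder_crop(
    net: MultiTaskCylinderNet, image: np.ndarray, crop: GridCrop
) -> tuple[CylinderParams, bool]:
    """Predict iso-crop-frame cylinder params for one windowed image.

    Origin = unweighted CoM of the thresholded (0.5) branch-1 segmentation;
    falls back to the regressed origin (flag True) if the segmentation is
    empty.  Normal is re-normalized; radius decoded; h fixed at 40 mm.
    """
    logits, pvec = net.forward(image[None, None].astype(np.float32))
    seg = logits.sigmoid().data[0, 0] >= 0.5
    n, o_reg, r = decode_params(pvec.data[0], crop.crop_extent_mm)
    fallback = False
    if seg.any():
        origin = np.argwhere(seg).mean(axis=0) * crop.iso_spacing_mm
    else:
        logger.warning("empty branch-1 segmentation; falling back to regressed origin")
        origin = o_reg
        fallback = True
    r = float(np.clip(r, 1.0, RADIUS_CAP_MM))
    p = CylinderParams(
        normal=n, origin_mm=origin, radius_mm=r, height_mm=FIXED_HEIGHT_MM, space="iso_crop"
    )
    return p, fallback


RADIUS_CAP_MM = 39.9


def predict_cylinder(
    net: MultiTaskCylinderNet, iso_image: np.ndarray, crop: GridCrop
) -> tuple[CylinderParams, bool]:
    """Full inference: crop-frame prediction mapped to acquisition space."""
    p_crop, fallback = predict_cylinder_crop(net, iso_image, crop)
    return map_params_between_spaces(p_crop, crop, "to_acquisition"), fallback


def cylinder_metrics(
    pred: CylinderParams, true: CylinderParams, grid: ImageVolume
) -> dict[str, float]:
    """Evaluation suite for a predicted/truth cylinder pair: mask Dice,
    Hausdorff distance (mm), radius absolute difference, origin Euclidean
    distance, normal cosine similarity."""
    from scipy import ndimage

    mp = reconstruct_cylinder_mask(pred, grid)
    mt = reconstruct_cylinder_mask(true, grid)
    inter = float(np.logical_and(mp, mt).sum())
    dice = 2 * inter / max(float(mp.sum() + mt.sum()), 1.0)
    if mp.any() and mt.any():
        dt_t = ndimage.distance_transform_edt(~mt, sampling=grid.spacing)
        dt_p = ndimage.distance_transform_edt(~mp, sampling=grid.spacing)
        hausdorff = float(max(dt_t[mp].max(), dt_p[mt].max()))
    else:
        hausdorff = float("inf")
    return {
        "dice": dice,
        "hausdorff_mm": hausdorff,
        "radius_abs_diff_mm": float(abs(pred.radius_mm - true.radius_mm)),
        "origin_dist_mm": float(np.linalg.norm(pred.origin_mm - true.origin_mm)),
        "normal_cos_sim": float(abs(np.dot(pred.normal, true.normal))),
    }
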