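"""Losses for the three branches, including differentiable cylinder rendering.

Branch-3 needs gradients to flow from a mask overlap back into the cylinder
parameters, so the binary membership test is relaxed to a product of
sigmoids::

    m(x) = sigmoid(k (r - rho(x))) * sigmoid(k (h/2 - |z'(x)|))

with sharpness k (1/mm): thresholding m at 0.5 recovers the exact cylinder
as k -> infinity.  The total loss is

    alpha * Dice_seg + beta * MSE_origin + delta * MSE_(normal, radius)
    + gamma * Dice_recon,

all weights defaulting to 1/4.  MSE terms operate on the normalized
parameter scale ([-1, 1] for every component) so no target dominates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .network import FIXED_HEIGHT_MM, RADIUS_SCALE_MM

__all__ = ["LossWeights", "dice_loss", "soft_reconstruct", "combined_loss"]

EPS = 1e-6


@dataclass
class LossWeights:
    """Branch weighting factors (alpha, beta, delta, gamma), defaults 1/4."""

    alpha: float = 0.25  # segmentation Dice
    beta: float = 0.25  # MSE on origin
    delta: float = 0.25  # MSE on normal + radius
    gamma: float = 0.25  # reconstruction Dice

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.delta, self.gamma) < 0:
            raise ValueError("loss weights must be non-negative")


def dice_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Soft Dice loss, 1 - 2|P.T| / (|P| + |T|), summed over the batch."""
    t = np.asarray(target, dtype=np.float32)
    inter = (pred * t).sum()
    denom = pred.sum() + float(t.sum())
    return 1.0 - (2.0 * inter + EPS) / (denom + EPS)


def _grid_coords(shape: tuple[int, int, int], spacing_mm: float) -> np.ndarray:
    """(M, 3) voxel-center mm coordinates of the reconstruction grid."""
    ax = [np.arange(s, dtype=np.float32) * spacing_mm for s in shape]
    g = np.meshgrid(*ax, indexing="ij")
    return np.stack([a.ravel() for a in g], axis=1)


def soft_reconstruct(
    pvec: Tensor,
    grid_shape: tuple[int, int, int],
    extent_mm: np.ndarray,
    sharpness: float = 50.0,
    height_mm: float = FIXED_HEIGHT_MM,
    spacing_mm: float | None = None,
) -> Tensor:
    """Differentiable cylinder membership from the tanh 7-vector.

    `pvec` is (N, 7): raw normal, normalized origin, rescaled radius.  The
    soft mask is evaluated at the centers of a `grid_shape` grid spanning
    `extent_mm` (the iso-crop frame).  Returns (N, M) values in (0, 1).
    """
    if not np.all(np.isfinite(pvec.data)):
        raise ValueError("non-finite parameter vector")
    extent = np.asarray(extent_mm, dtype=np.float32)
    if spacing_mm is None:
        spacing_mm = float(extent[0] / grid_shape[0])
    X = _grid_coords(grid_shape, spacing_mm)[None, :, :]  # (1, M, 3)

    nb = pvec.shape[0]
    nraw = pvec[:, 0:3].reshape(nb, 1, 3)
    inv_norm = (nraw * nraw).sum(axis=2, keepdims=True).sqrt(EPS).pow(-1.0)
    n = nraw * inv_norm
    origin = (pvec[:, 3:6].reshape(nb, 1, 3) + 1.0) * (0.5 * extent)
    radius = (pvec[:, 6].reshape(nb, 1) + 1.0) * (0.5 * RADIUS_SCALE_MM)

    d = Tensor(X) - origin  # (N, M, 3)
    z = (d * n).sum(axis=2)
    rho = ((d * d).sum(axis=2) - z * z).sqrt(EPS)
    absz = (z * z).sqrt(EPS)
    k = float(sharpness)
    return ((radius - rho) * k).sigmoid() * ((height_mm / 2.0 - absz) * k).sigmoid()


def combined_loss(
    seg_logits: Tensor,
    seg_true: np.ndarray,
    pvec_pred: Tensor,
    pvec_true: np.ndarray,
    weights: LossWeights | None = None,
    recon_grid_shape: tuple[int, int, int] | None = None,
    extent_mm: np.ndarray | None = None,
    sharpness: float = 50.0,
) -> tuple[Tensor, dict[str, float]]:
    """Total three-branch loss and its per-term values.

    Zeroing a weight removes that branch entirely (its term is not even
    evaluated), which is how the ablation configurations are expressed.
    """
    w = weights or LossWeights()
    pt = np.asarray(pvec_true, dtype=np.float32)
    if pt.shape != pvec_pred.shape:
        raise ValueError(f"parameter shapes differ: {pt.shape} vs {pvec_pred.shape}")
    terms: dict[str, float] = {}
    total = Tensor(0.0)

    if w.alpha > 0:
        l_seg = dice_loss(seg_logits.sigmoid(), seg_true)
        terms["dice_seg"] = float(l_seg.data)
        total = total + w.alpha * l_seg
    if w.beta > 0:
        diff = pvec_pred[:, 3:6] - pt[:, 3:6]
        l_origin = (diff * diff).mean()
        terms["mse_origin"] = float(l_origin.data)
        total = total + w.beta * l_origin
    if w.delta > 0:
        idx = (slice(None), [0, 1, 2, 6])
        diff = pvec_pred[idx] - pt[:, [0, 1, 2, 6]]
        l_nr = (diff * diff).mean()
        terms["mse_normal_radius"] = float(l_nr.data)
        total = total + w.delta * l_nr
    if w.gamma > 0:
        if recon_grid_shape is None or extent_mm is None:
            raise ValueError("branch-3 needs recon_grid_shape and extent_mm")
        soft = soft_reconstruct(pvec_pred, recon_grid_shape, extent_mm, sharpness)
        # target resampled onto the reconstruction grid by striding
        t = np.asarray(seg_true, dtype=np.float32)
        strides = tuple(t.shape[i + 2] // recon_grid_shape[i] for i in range(3))
        tt = t[:, 0, :: strides[0], :: strides[1], :: strides[2]].reshape(t.shape[0], -1)
        l_recon = dice_loss(soft, tt)
        terms["dice_recon"] = float(l_recon.data)
        total = total + w.gamma * l_recon

    terms["total"] = float(total.data)
    return total, terms
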