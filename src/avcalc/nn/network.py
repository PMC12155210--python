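"""Three-branch multi-task network for cylinder ROI prediction.

A volumetric encoder-decoder (U-Net-style, additive skips) reads the
windowed isotropic CT volume and produces:

* branch-1 — semantic segmentation logits of the cylinder ROI;
* branch-2 — a 7-vector of cylinder parameters (normal μx, μy, μz; origin
  x0, y0, z0 normalized to [-1, 1] over the crop extent; radius rescaled by
  r_rescaled = 2 (r / 40) - 1), squashed by tanh after an MLP block
  (FullyConnected, LeakyReLU, LayerNorm, Dropout) fed from the
  adaptive-average-pooled encoder bottom;
* branch-3 — a differentiable cylinder mask reconstructed from the predicted
  parameters (see :mod:`avcalc.nn.losses`), compared to the label with a
  Dice loss.

The height is not regressed: h = 40 mm for every valve ROI.  At inference the
origin is taken from the center of mass of the thresholded branch-1
segmentation (the CoM linkage), which is far more accurate than regressing
the origin directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, avg_pool3d, conv3d, dropout, layer_norm, upsample3d

__all__ = [
    "NetConfig",
    "MultiTaskCylinderNet",
    "build_network",
    "encode_radius",
    "decode_radius",
    "encode_params",
    "decode_params",
    "N_PARAMS",
    "FIXED_HEIGHT_MM",
]

N_PARAMS = 7
FIXED_HEIGHT_MM = 40.0
RADIUS_SCALE_MM = 40.0


def encode_radius(r_mm: float) -> float:
    """Map radius (0, 40] mm to [-1, 1]: r_rescaled = 2 (r / 40) - 1."""
    if not (0.0 < r_mm <= RADIUS_SCALE_MM):
        raise ValueError(f"radius {r_mm} mm outside (0, {RADIUS_SCALE_MM}]")
    return 2.0 * (r_mm / RADIUS_SCALE_MM) - 1.0


def decode_radius(v: float) -> float:
    """Inverse of :func:`encode_radius`."""
    if not (-1.0 < v <= 1.0):
        raise ValueError(f"encoded radius {v} outside (-1, 1]")
    return (v + 1.0) / 2.0 * RADIUS_SCALE_MM


def encode_params(
    normal: np.ndarray, origin_crop_mm: np.ndarray, radius_mm: float, extent_mm: np.ndarray
) -> np.ndarray:
    """Pack (normal, origin, radius) into the 7-vector regression target.

    Origin coordinates are normalized to [-1, 1] over the crop extent so all
    seven targets share the tanh output scale.
    """
    o = 2.0 * np.asarray(origin_crop_mm) / np.asarray(extent_mm) - 1.0
    return np.concatenate([np.asarray(normal), o, [encode_radius(radius_mm)]]).astype(np.float32)


def decode_params(vec: np.ndarray, extent_mm: np.ndarray):
    """Unpack the 7-vector: (unit normal, origin mm in crop frame, radius mm)."""
    vec = np.asarray(vec, dtype=float)
    n = vec[:3]
    nn = np.linalg.norm(n)
    if nn < 1e-6:
        raise ValueError("degenerate normal in parameter vector")
    o = (vec[3:6] + 1.0) / 2.0 * np.asarray(extent_mm)
    r = float(np.clip(vec[6], -1.0 + 1e-6, 1.0))
    return n / nn, o, decode_radius(r)


@dataclass
class NetConfig:
    """Architecture/configuration of the multi-task network.

    `channels` are the encoder widths per resolution level (halving spatial
    size between levels); the last entry is the latent width that the pooled
    descriptor and MLP see.  `stem_pool` optionally downsamples the input
    before the first convolution so desk-scale runs stay cheap; segmentation
    logits are produced at stem resolution and nearest-upsampled back.
    """

    input_shape: tuple[int, int, int] = (64, 64, 64)
    stem_pool: int = 2
    channels: tuple[int, ...] = (8, 16, 32)
    mlp_hidden: int = 64
    dropout: float = 0.1
    leaky_slope: float = 0.01
    n_params: int = N_PARAMS
    seed: int = 0

    @classmethod
    def full_size(cls) -> "NetConfig":
        """Acquisition-scale preset: 176x176x128 input, 256-wide latent of
        spatial shape 11x11x8."""
        return cls(
            input_shape=(176, 176, 128),
            stem_pool=1,
            channels=(16, 32, 64, 128, 256),
            mlp_hidden=256,
        )

    def check(self) -> None:
        div = self.stem_pool * 2 ** (len(self.channels) - 1)
        if any(s % div for s in self.input_shape):
            raise ValueError(
                f"input shape {self.input_shape} not divisible by {div} "
                f"(stem_pool x 2^(levels-1))"
            )

    @property
    def latent_channels(self) -> int:
        return self.channels[-1]

    @property
    def latent_shape(self) -> tuple[int, ...]:
        div = self.stem_pool * 2 ** (len(self.channels) - 1)
        return tuple(s // div for s in self.input_shape)


class MultiTaskCylinderNet:
    """Encoder-decoder with a segmentation head and a parameter-regression
    head (pooled latent -> MLP -> tanh 7-vector)."""

    def __init__(self, config: NetConfig):
        config.check()
        self.config = config
        rng = np.random.default_rng([config.seed, 77])
        self.params: dict[str, Tensor] = {}
        ch = config.channels

        def conv_w(name, cin, cout, k=3):
            std = np.sqrt(2.0 / (cin * k**3))
            self.params[f"{name}.w"] = Tensor(
                rng.normal(0, std, (cout, cin, k, k, k)), requires_grad=True
            )
            self.params[f"{name}.b"] = Tensor(np.zeros(cout), requires_grad=True)

        def fc_w(name, cin, cout):
            std = np.sqrt(2.0 / cin)
            self.params[f"{name}.w"] = Tensor(rng.normal(0, std, (cin, cout)), requires_grad=True)
            self.params[f"{name}.b"] = Tensor(np.zeros(cout), requires_grad=True)

        conv_w("enc0", 1, ch[0])
        for i in range(1, len(ch)):
            conv_w(f"enc{i}", ch[i - 1], ch[i])
        for i in range(len(ch) - 2, -1, -1):
            conv_w(f"dec{i}", ch[i + 1], ch[i])
        conv_w("seg", ch[0], 1)
        fc_w("mlp0", ch[-1], config.mlp_hidden)
        self.params["ln.g"] = Tensor(np.ones(config.mlp_hidden), requires_grad=True)
        self.params["ln.b"] = Tensor(np.zeros(config.mlp_hidden), requires_grad=True)
        fc_w("mlp1", config.mlp_hidden, config.n_params)
        # small output init: regression starts near the tanh origin
        self.params["mlp1.w"].data *= 0.05
        self._drop_rng = np.random.default_rng([config.seed, 88])

    @property
    def pooled_descriptor_length(self) -> int:
        """Length of the adaptive-average-pooled latent vector."""
        return self.config.latent_channels

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def n_weights(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def forward(self, x: np.ndarray | Tensor, training: bool = False):
        """x: (N, 1, X, Y, Z) windowed intensities.

        Returns (segmentation logits at input resolution, tanh 7-vector).
        """
        cfg = self.config
        if isinstance(x, np.ndarray):
            if x.ndim != 5 or x.shape[2:] != cfg.input_shape:
                raise ValueError(f"expected input (N, 1, {cfg.input_shape}), got {x.shape}")
            x = Tensor(x)
        P = self.params
        slope = cfg.leaky_slope

        h = avg_pool3d(x, cfg.stem_pool) if cfg.stem_pool > 1 else x
        feats = []
        for i in range(len(cfg.channels)):
            if i > 0:
                h = avg_pool3d(h, 2)
            h = conv3d(h, P[f"enc{i}.w"], P[f"enc{i}.b"]).leaky_relu(slope)
            feats.append(h)

        # branch-2: pooled latent descriptor -> MLP -> tanh params
        lat = h.mean(axis=(2, 3, 4))  # adaptive average pool to (N, C)
        m = (lat @ P["mlp0.w"] + P["mlp0.b"]).leaky_relu(slope)
        m = layer_norm(m, P["ln.g"], P["ln.b"])
        m = dropout(m, cfg.dropout, self._drop_rng, training)
        pvec = (m @ P["mlp1.w"] + P["mlp1.b"]).tanh()

        # branch-1: decoder with additive skips -> seg logits
        # (convolve at the coarse level, then upsample: much cheaper than
        # convolving at the fine level and equally adequate for smooth ROIs)
        d = feats[-1]
        for i in range(len(cfg.channels) - 2, -1, -1):
            d = conv3d(d, P[f"dec{i}.w"], P[f"dec{i}.b"]).leaky_relu(slope)
            d = upsample3d(d, 2)
            d = d + feats[i]
        logits = conv3d(d, P["seg.w"], P["seg.b"])
        if cfg.stem_pool > 1:
            logits = upsample3d(logits, cfg.stem_pool)
        return logits, pvec

    # -- checkpointing ---------------------------------------------------
    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, sd: dict) -> None:
        for k, v in sd.items():
            self.params[k].data = np.asarray(v, dtype=np.float32)

    def save(self, path: str) -> None:
        import hashlib, json

        cfg = self.config
        cfg_json = json.dumps(
            {
                "input_shape": cfg.input_shape,
                "stem_pool": cfg.stem_pool,
                "channels": cfg.channels,
                "mlp_hidden": cfg.mlp_hidden,
                "dropout": cfg.dropout,
                "leaky_slope": cfg.leaky_slope,
                "n_params": cfg.n_params,
                "seed": cfg.seed,
            }
        )
        np.savez_compressed(
            path,
            __config__=cfg_json,
            __config_hash__=hashlib.sha256(cfg_json.encode()).hexdigest(),
            **self.state_dict(),
        )

    @classmethod
    def load(cls, path: str) -> "MultiTaskCylinderNet":
        import json

        with np.load(path, allow_pickle=False) as z:
            cfg_d = json.loads(str(z["__config__"]))
            cfg = NetConfig(
                input_shape=tuple(cfg_d["input_shape"]),
                stem_pool=cfg_d["stem_pool"],
                channels=tuple(cfg_d["channels"]),
                mlp_hidden=cfg_d["mlp_hidden"],
                dropout=cfg_d["dropout"],
                leaky_slope=cfg_d["leaky_slope"],
                n_params=cfg_d["n_params"],
                seed=cfg_d["seed"],
            )
            net = cls(cfg)
            net.load_state_dict({k: z[k] for k in z.files if not k.startswith("__")})
        return net


def build_network(config: NetConfig | None = None) -> MultiTaskCylinderNet:
    """Construct the model (validates the input-shape/architecture match)."""
    return MultiTaskCylinderNet(config or NetConfig())
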