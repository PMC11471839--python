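"""Generator / discriminator networks and the identity (skip) block.

The networks are small, CPU-friendly, and written directly on numpy arrays
with explicit forward and backward passes.  The generator conditions on the
zero-filled masked image plus the mask (stacked as channels), runs them
through a small convolutional stem followed by one identity block, then a
fully connected trunk that also receives the noise vector, and squashes the
output to [0, 1] with a sigmoid.  When compositing is enabled the observed
pixels of the input pass through unchanged:

    output = mask * raw_generation + (1 - mask) * masked_image

The identity block computes ``conv3x3(act(conv1x1(x))) + x``; with all block
weights zero it is exactly the identity map, and its skip path guarantees a
unit Jacobian term so gradients always reach the input.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Literal

import numpy as np

from .errors import ConfigurationError, ShapeError

__all__ = [
    "IdentityBlockConfig",
    "GeneratorConfig",
    "DiscriminatorConfig",
    "ModelParams",
    "init_generator",
    "init_discriminator",
    "identity_block_forward",
    "generator_forward",
    "discriminator_forward",
    "CHECKPOINT_VERSION",
]

CHECKPOINT_VERSION = 1

Activation = Literal["relu", "leaky_relu"]


@dataclass(frozen=True)
class IdentityBlockConfig:
    in_channels: int = 8
    mid_channels: int = 8
    activation: Activation = "relu"


@dataclass(frozen=True)
class GeneratorConfig:
    image_shape: tuple[int, int, int] = (16, 16, 1)
    noise_dim: int = 32
    hidden_sizes: tuple[int, ...] = (256, 256)
    feature_channels: int = 8
    mid_channels: int = 8
    use_identity_block: bool = True
    composite_output: bool = True

    def __post_init__(self) -> None:
        if self.noise_dim < 1:
            raise ConfigurationError("noise_dim must be >= 1")
        if len(self.image_shape) != 3:
            raise ConfigurationError("image_shape must be (H, W, C)")


@dataclass(frozen=True)
class DiscriminatorConfig:
    image_shape: tuple[int, int, int] = (16, 16, 1)
    hidden_sizes: tuple[int, ...] = (256, 256)
    leaky_slope: float = 0.2


@dataclass
class ModelParams:
    """Named parameter arrays plus the architecture config that shaped them."""

    kind: str  # "generator" | "discriminator"
    config: dict = field(default_factory=dict)
    arrays: dict = field(default_factory=dict)
    version: int = CHECKPOINT_VERSION

    def copy(self) -> "ModelParams":
        return ModelParams(
            kind=self.kind,
            config=json.loads(json.dumps(self.config)),
            arrays={k: v.copy() for k, v in self.arrays.items()},
            version=self.version,
        )

    def save(self, path) -> None:
        meta = json.dumps(
            {"kind": self.kind, "config": self.config, "version": self.version}
        )
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.arrays)

    @classmethod
    def load(cls, path) -> "ModelParams":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            arrays = {k: data[k].copy() for k in data.files if k != "__meta__"}
        return cls(kind=meta["kind"], config=meta["config"],
                   arrays=arrays, version=meta["version"])


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def _relu(x):
    return np.maximum(x, 0.0)


def _leaky(x, slope):
    return np.where(x > 0, x, slope * x)


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padding convolution, kernel size 1 or 3. x: (N, Cin, H, W)."""
    k = w.shape[2]
    if k == 1:
        y = np.einsum("oc,nchw->nohw", w[:, :, 0, 0], x)
    else:
        n, c, h, wd = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        y = np.zeros((n, w.shape[0], h, wd))
        for i in range(3):
            for j in range(3):
                y += np.einsum("oc,nchw->nohw", w[:, :, i, j],
                               xp[:, :, i : i + h, j : j + wd])
    return y + b[None, :, None, None]


def conv2d_backward(dy: np.ndarray, x: np.ndarray, w: np.ndarray):
    """Gradients of ``conv2d``: returns (dx, dw, db)."""
    k = w.shape[2]
    db = dy.sum(axis=(0, 2, 3))
    if k == 1:
        dw = np.einsum("nohw,nchw->oc", dy, x)[:, :, None, None]
        dx = np.einsum("oc,nohw->nchw", w[:, :, 0, 0], dy)
        return dx, dw, db
    n, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dw = np.zeros_like(w)
    dxp = np.zeros_like(xp)
    for i in range(3):
        for j in range(3):
            patch = xp[:, :, i : i + h, j : j + wd]
            dw[:, :, i, j] = np.einsum("nohw,nchw->oc", dy, patch)
            dxp[:, :, i : i + h, j : j + wd] += np.einsum(
                "oc,nohw->nchw", w[:, :, i, j], dy
            )
    return dxp[:, :, 1:-1, 1:-1], dw, db


# ---------------------------------------------------------------------------
# identity block
# ---------------------------------------------------------------------------


def identity_block_forward(
    features: np.ndarray, params: dict, activation: Activation = "relu"
) -> np.ndarray:
    """``conv3x3(act(conv1x1(x))) + x`` on an H×W×C feature grid.

    The activation acts only on the inner branch; the skip path is untouched,
    so zero weights and biases reproduce the input exactly.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
    c_in = params["w1"].shape[1]
    if x.shape[2] != c_in:
        raise ShapeError(
            f"identity block expects {c_in} channels, got {x.shape[2]}"
        )
    xn = np.transpose(x, (2, 0, 1))[None]  # (1, C, H, W)
    out, _ = _identity_block(xn, params, activation)
    res = np.transpose(out[0], (1, 2, 0))
    return res if features.ndim == 3 else res[:, :, 0]


def _identity_block(x, params, activation):
    z1 = conv2d(x, params["w1"], params["b1"])
    a1 = _relu(z1) if activation == "relu" else _leaky(z1, 0.2)
    z2 = conv2d(a1, params["w2"], params["b2"])
    return z2 + x, (x, z1, a1)


def _identity_block_backward(dy, cache, params, activation):
    x, z1, a1 = cache
    da1, dw2, db2 = conv2d_backward(dy, a1, params["w2"])
    if activation == "relu":
        dz1 = da1 * (z1 > 0)
    else:
        dz1 = da1 * np.where(z1 > 0, 1.0, 0.2)
    dx_branch, dw1, db1 = conv2d_backward(dz1, x, params["w1"])
    return dy + dx_branch, {"w1": dw1, "b1": db1, "w2": dw2, "b2": db2}


def init_identity_block(
    cfg: IdentityBlockConfig, rng: np.random.Generator
) -> dict:
    c, m = cfg.in_channels, cfg.mid_channels
    return {
        "w1": _glorot(rng, (m, c, 1, 1), c, m),
        "b1": np.zeros(m),
        "w2": _glorot(rng, (c, m, 3, 3), m * 9, c * 9),
        "b2": np.zeros(c),
    }


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


def init_generator(cfg: GeneratorConfig, seed: int) -> ModelParams:
    """Seeded Glorot initialization of all generator parameters."""
    rng = np.random.default_rng(seed)
    h, w, c = cfg.image_shape
    f = cfg.feature_channels
    arrays = {
        "stem1_w": _glorot(rng, (f, c + 1, 1, 1), c + 1, f),
        "stem1_b": np.zeros(f),
        "stem2_w": _glorot(rng, (f, f, 3, 3), f * 9, f * 9),
        "stem2_b": np.zeros(f),
    }
    if cfg.use_identity_block:
        blk = init_identity_block(
            IdentityBlockConfig(in_channels=f, mid_channels=cfg.mid_channels), rng
        )
        arrays.update({f"idb_{k}": v for k, v in blk.items()})
    flat = f * h * w + cfg.noise_dim
    sizes = [flat, *cfg.hidden_sizes, h * w * c]
    for li in range(len(sizes) - 1):
        arrays[f"fc{li}_w"] = _glorot(
            rng, (sizes[li + 1], sizes[li]), sizes[li], sizes[li + 1]
        )
        arrays[f"fc{li}_b"] = np.zeros(sizes[li + 1])
    return ModelParams(kind="generator", config=asdict(cfg), arrays=arrays)


def _gen_cfg(params: ModelParams) -> GeneratorConfig:
    c = dict(params.config)
    c["image_shape"] = tuple(c["image_shape"])
    c["hidden_sizes"] = tuple(c["hidden_sizes"])
    return GeneratorConfig(**c)


def generator_forward_batch(
    images: np.ndarray, masks: np.ndarray, noise: np.ndarray, params: ModelParams
):
    """Batched raw generation; returns (raw (N,H,W,C) in [0,1], cache)."""
    cfg = _gen_cfg(params)
    h, w, c = cfg.image_shape
    a = params.arrays
    n = images.shape[0]
    if noise.shape != (n, cfg.noise_dim):
        raise ConfigurationError(
            f"noise shape {noise.shape} != ({n}, {cfg.noise_dim})"
        )
    x_img = np.transpose(images.reshape(n, h, w, c), (0, 3, 1, 2))
    x = np.concatenate([x_img, masks.reshape(n, 1, h, w)], axis=1)

    z1 = conv2d(x, a["stem1_w"], a["stem1_b"])
    a1 = _relu(z1)
    z2 = conv2d(a1, a["stem2_w"], a["stem2_b"])
    a2 = _relu(z2)
    if cfg.use_identity_block:
        blk = {k[4:]: v for k, v in a.items() if k.startswith("idb_")}
        ib, ib_cache = _identity_block(a2, blk, "relu")
    else:
        ib, ib_cache = a2, None
    flat = np.concatenate([ib.reshape(n, -1), noise], axis=1)

    acts = [flat]
    pre = []
    n_fc = sum(1 for k in a if k.endswith("_w") and k.startswith("fc"))
    cur = flat
    for li in range(n_fc):
        z = cur @ a[f"fc{li}_w"].T + a[f"fc{li}_b"]
        pre.append(z)
        cur = _relu(z) if li < n_fc - 1 else _sigmoid(z)
        acts.append(cur)
    raw = cur.reshape(n, h, w, c)
    cache = (x, z1, a1, z2, a2, ib_cache, flat, pre, acts, cfg)
    return raw, cache


def generator_backward_batch(d_raw: np.ndarray, cache, params: ModelParams):
    """Gradients of all generator parameters given d(loss)/d(raw)."""
    x, z1, a1, z2, a2, ib_cache, flat, pre, acts, cfg = cache
    a = params.arrays
    h, w, c = cfg.image_shape
    n = d_raw.shape[0]
    grads = {}
    n_fc = len(pre)
    cur = d_raw.reshape(n, -1)
    for li in reversed(range(n_fc)):
        z = pre[li]
        if li == n_fc - 1:
            s = acts[li + 1]
            dz = cur * s * (1.0 - s)
        else:
            dz = cur * (z > 0)
        grads[f"fc{li}_w"] = dz.T @ acts[li]
        grads[f"fc{li}_b"] = dz.sum(axis=0)
        cur = dz @ a[f"fc{li}_w"]
    d_noise = cur[:, -cfg.noise_dim:]
    d_ib = cur[:, : -cfg.noise_dim].reshape(n, cfg.feature_channels, h, w)
    if cfg.use_identity_block:
        blk = {k[4:]: v for k, v in a.items() if k.startswith("idb_")}
        d_a2, bg = _identity_block_backward(d_ib, ib_cache, blk, "relu")
        grads.update({f"idb_{k}": v for k, v in bg.items()})
    else:
        d_a2 = d_ib
    dz2 = d_a2 * (z2 > 0)
    d_a1, grads["stem2_w"], grads["stem2_b"] = conv2d_backward(dz2, a1, a["stem2_w"])
    dz1 = d_a1 * (z1 > 0)
    _, grads["stem1_w"], grads["stem1_b"] = conv2d_backward(dz1, x, a["stem1_w"])
    return grads, d_noise


def generator_forward(
    masked_image: np.ndarray,
    mask: np.ndarray,
    noise: np.ndarray,
    params: ModelParams,
) -> np.ndarray:
    """Impute one network-scale image ([0, 1] values).

    Missing entries of ``masked_image`` should be zero-filled; the mask
    (1 = missing) is authoritative.  With ``composite_output`` on, observed
    pixels pass through unchanged.
    """
    cfg = _gen_cfg(params)
    h, w, c = cfg.image_shape
    img = np.asarray(masked_image, dtype=float).reshape(1, h, w, c)
    msk = np.asarray(mask, dtype=float).reshape(1, h, w)
    noise = np.asarray(noise, dtype=float).reshape(1, -1)
    raw, _ = generator_forward_batch(img, msk, noise, params)
    if cfg.composite_output:
        out = msk[..., None] * raw + (1.0 - msk[..., None]) * img
    else:
        out = raw
    out = out.reshape(h, w, c)
    return out if np.asarray(masked_image).ndim == 3 else out[:, :, 0]


# ---------------------------------------------------------------------------
# discriminator
# ---------------------------------------------------------------------------


def init_discriminator(cfg: DiscriminatorConfig, seed: int) -> ModelParams:
    rng = np.random.default_rng(seed)
    h, w, c = cfg.image_shape
    sizes = [h * w * c, *cfg.hidden_sizes, 1]
    arrays = {}
    for li in range(len(sizes) - 1):
        arrays[f"fc{li}_w"] = _glorot(
            rng, (sizes[li + 1], sizes[li]), sizes[li], sizes[li + 1]
        )
        arrays[f"fc{li}_b"] = np.zeros(sizes[li + 1])
    return ModelParams(kind="discriminator", config=asdict(cfg), arrays=arrays)


def discriminator_logits(images: np.ndarray, params: ModelParams):
    """Batched logits; images (N, H, W, C) or (N, H*W*C). Returns (z, cache)."""
    cfg = DiscriminatorConfig(
        image_shape=tuple(params.config["image_shape"]),
        hidden_sizes=tuple(params.config["hidden_sizes"]),
        leaky_slope=params.config.get("leaky_slope", 0.2),
    )
    h, w, c = cfg.image_shape
    n = images.shape[0]
    expected = h * w * c
    flat = np.asarray(images, dtype=float).reshape(n, -1)
    if flat.shape[1] != expected:
        raise ShapeError(
            f"discriminator expects {expected} values per image, got {flat.shape[1]}"
        )
    acts, pre = [flat], []
    cur = flat
    n_fc = len(cfg.hidden_sizes) + 1
    a = params.arrays
    for li in range(n_fc):
        z = cur @ a[f"fc{li}_w"].T + a[f"fc{li}_b"]
        pre.append(z)
        cur = _leaky(z, cfg.leaky_slope) if li < n_fc - 1 else z
        acts.append(cur)
    return cur[:, 0], (acts, pre, cfg)


def discriminator_backward(dz_out: np.ndarray, cache, params: ModelParams):
    """Gradients given d(loss)/d(logit); returns (grads, d_input_flat)."""
    acts, pre, cfg = cache
    a = params.arrays
    grads = {}
    n_fc = len(pre)
    cur = dz_out[:, None]
    for li in reversed(range(n_fc)):
        if li < n_fc - 1:
            cur = cur * np.where(pre[li] > 0, 1.0, cfg.leaky_slope)
        grads[f"fc{li}_w"] = cur.T @ acts[li]
        grads[f"fc{li}_b"] = cur.sum(axis=0)
        cur = cur @ a[f"fc{li}_w"]
    return grads, cur


def discriminator_forward(image: np.ndarray, params: ModelParams) -> float:
    """Authenticity score in [0, 1] for one network-scale image."""
    img = np.asarray(image, dtype=float)
    z, _ = discriminator_logits(img[None], params)
    return float(_sigmoid(z)[0])
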