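"""Adversarial training with the neutrosophic neighborhood loss.

One epoch alternates a discriminator step (binary cross-entropy on real vs.
composited fake images) with a generator step whose loss is

    adversarial_weight * BCE(D(fake), real) + lambda * mean neutrosophic loss

where the neutrosophic term compares 8-connected neighborhood statistics of
the composited output against the ground truth.  The threshold gate of the
neutrosophic loss is non-differentiable and is treated as a constant during
gradient computation.  Once the mean per-pixel neutrosophic loss falls below
``fine_tune_threshold`` the run enters a fine-tuning phase: generator-only
updates at one tenth of the learning rate.  A patience rule on the
neutrosophic loss provides early stopping.  All randomness flows from the
single master seed via ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    PreconditionError,
    ShapeError,
    TrainingDivergenceError,
)
from .model import (
    DiscriminatorConfig,
    GeneratorConfig,
    ModelParams,
    discriminator_backward,
    discriminator_logits,
    generator_backward_batch,
    generator_forward_batch,
    init_discriminator,
    init_generator,
)
from .neutro import NEIGHBOR_OFFSETS, LossConfig
from .synthetic import MaskedImage

__all__ = [
    "TrainConfig",
    "EpochRecord",
    "TrainHistory",
    "train",
    "impute",
    "mean_fill",
    "mode_collapse_diagnostic",
    "should_stop",
    "zero_noise_weights",
]

log = logging.getLogger("neutrofill.training")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 16
    lr_generator: float = 2e-4
    lr_discriminator: float = 2e-4
    adversarial_weight: float = 1.0
    neutrosophic_weight: float = 10.0
    loss_config: LossConfig = field(default_factory=LossConfig)
    fine_tune_threshold: float = 1e-3
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.early_stop_patience < 1:
            raise ConfigurationError("epochs, batch_size and patience must be >= 1")
        for name in ("lr_generator", "lr_discriminator",
                     "adversarial_weight", "neutrosophic_weight"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass
class EpochRecord:
    epoch: int
    disc_loss: float
    gen_adv_loss: float
    neutro_total: float
    neutro_mean: float
    gated_count: int
    gen_total_loss: float
    fine_tune: bool
    stop: bool


@dataclass
class TrainHistory:
    records: list = field(default_factory=list)
    checkpoints: dict = field(default_factory=dict)

    @property
    def neutro_means(self) -> list[float]:
        return [r.neutro_mean for r in self.records]


# ---------------------------------------------------------------------------
# neutrosophic loss + gradient, batched, network scale
# ---------------------------------------------------------------------------


def _neighbor_sum(arr: np.ndarray) -> np.ndarray:
    """Sum over the 8-connected neighbors with zero padding; arr (..., H, W)."""
    h, w = arr.shape[-2:]
    p = np.pad(arr, [(0, 0)] * (arr.ndim - 2) + [(1, 1), (1, 1)])
    out = np.zeros_like(arr)
    for dr, dc in NEIGHBOR_OFFSETS:
        out += p[..., 1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
    return out


def neutro_loss_grad(u_gen: np.ndarray, u_real: np.ndarray, threshold: float):
    """Batched neutrosophic neighborhood loss and its gradient.

    ``u_gen``/``u_real`` hold network-scale intensities in [0, 1] with shape
    (N, H, W).  Uses the default loss settings (valid borders, uniform
    weights, all pixels, mean-triple aggregation); the gate is a constant
    w.r.t. the gradient.  Returns (total, gated_count, grad) with ``grad``
    shaped like ``u_gen``.
    """
    h, w = u_gen.shape[-2:]
    counts = _neighbor_sum(np.ones((1, h, w)))  # (1, H, W), 3/5/8 pattern

    def comps(u):
        return np.stack([1.0 - u, u * (1.0 - u), u], axis=1)  # (N, 3, H, W)

    a_gen = _neighbor_sum(comps(u_gen)) / counts[:, None]
    a_real = _neighbor_sum(comps(u_real)) / counts[:, None]
    d = a_gen - a_real
    gate = np.all(np.abs(d) < threshold, axis=1)  # (N, H, W)
    keep = ~gate
    total = float(np.sum(d * d * keep[:, None]))
    # S_c = 2 * keep * D_c / n; dL/dcomp_c(q) = neighbor-sum of S_c
    s = 2.0 * d * keep[:, None] / counts[:, None]
    adj = _neighbor_sum(s)
    grad = -adj[:, 0] + (1.0 - 2.0 * u_gen) * adj[:, 1] + adj[:, 2]
    return total, int(gate.sum()), grad


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, arrays: dict, lr: float, betas=(0.5, 0.999), eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.v = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.t = 0

    def step(self, arrays: dict, grads: dict, lr_scale: float = 1.0) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            arrays[k] -= (self.lr * lr_scale) * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _bce_from_logits(z: np.ndarray, target: float) -> float:
    # mean of softplus(z) - target * z, numerically stable
    sp = np.where(z > 0, z + np.log1p(np.exp(-np.abs(z))),
                  np.log1p(np.exp(-np.abs(z))))
    return float(np.mean(sp - target * z))


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _stack_dataset(dataset: Sequence[MaskedImage]):
    domain = dataset[0].domain
    truths = np.stack([it.truth / domain.max_value for it in dataset])
    masks = np.stack([it.mask.astype(float) for it in dataset])
    corrupted = truths * (1.0 - masks)
    return truths, masks, corrupted, domain


def train(
    dataset: Sequence[MaskedImage],
    config: TrainConfig,
    gen_config: Optional[GeneratorConfig] = None,
    disc_config: Optional[DiscriminatorConfig] = None,
    out_dir: Optional[Path] = None,
):
    """Run the full adversarial loop; returns (gen, disc, history).

    Every dataset item must carry its ground truth.  When ``out_dir`` is
    given, generator/discriminator checkpoints, a machine-readable per-epoch
    log and a run manifest are written there.
    """
    if len(dataset) == 0:
        raise PreconditionError("dataset must be non-empty")
    if any(it.truth is None for it in dataset):
        raise PreconditionError("training requires ground-truth images")
    truths, masks, corrupted, domain = _stack_dataset(dataset)
    n_items, h, w = truths.shape

    if gen_config is None:
        gen_config = GeneratorConfig(image_shape=(h, w, 1))
    if disc_config is None:
        disc_config = DiscriminatorConfig(
            image_shape=gen_config.image_shape,
            hidden_sizes=gen_config.hidden_sizes,
        )

    ss = np.random.SeedSequence(config.seed)
    s_gen, s_disc, s_loop = ss.spawn(3)
    gen = init_generator(gen_config, int(s_gen.generate_state(1)[0]) % (2**31))
    disc = init_discriminator(disc_config, int(s_disc.generate_state(1)[0]) % (2**31))
    rng = np.random.default_rng(s_loop)

    opt_g = _Adam(gen.arrays, config.lr_generator)
    opt_d = _Adam(disc.arrays, config.lr_discriminator)

    history = TrainHistory()
    fine_tune_active = math.isinf(config.fine_tune_threshold) and (
        config.fine_tune_threshold > 0
    )
    nd = gen_config.noise_dim
    pixels_per_image = h * w

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n_items)
        d_losses, adv_losses = [], []
        neutro_total_epoch, gated_epoch = 0.0, 0
        for start in range(0, n_items, config.batch_size):
            idx = order[start : start + config.batch_size]
            nb = len(idx)
            u_true, msk, u_corr = truths[idx], masks[idx], corrupted[idx]
            noise = rng.standard_normal((nb, nd))

            raw, cache = generator_forward_batch(
                u_corr[..., None], msk, noise, gen
            )
            raw2 = raw[..., 0]
            fake = msk * raw2 + (1.0 - msk) * u_corr

            # --- discriminator step (skipped in the fine-tuning phase) ---
            z_real, c_real = discriminator_logits(u_true[..., None], disc)
            z_fake, c_fake = discriminator_logits(fake[..., None], disc)
            d_loss = _bce_from_logits(z_real, 1.0) + _bce_from_logits(z_fake, 0.0)
            if not fine_tune_active:
                g_real, _ = discriminator_backward(
                    (_sigmoid(z_real) - 1.0) / nb, c_real, disc
                )
                g_fake, _ = discriminator_backward(
                    _sigmoid(z_fake) / nb, c_fake, disc
                )
                opt_d.step(disc.arrays, {k: g_real[k] + g_fake[k] for k in g_real})

            # --- generator step ---
            z_g, c_g = discriminator_logits(fake[..., None], disc)
            adv_loss = _bce_from_logits(z_g, 1.0)
            _, d_in = discriminator_backward(
                config.adversarial_weight * (_sigmoid(z_g) - 1.0) / nb, c_g, disc
            )
            d_fake = d_in.reshape(nb, h, w)

            n_total, n_gated, n_grad = neutro_loss_grad(
                fake, u_true, config.loss_config.threshold
            )
            lam = config.neutrosophic_weight
            d_fake = d_fake + lam * n_grad / (nb * pixels_per_image)

            d_raw = (msk * d_fake)[..., None]  # compositing pass-through
            grads, _ = generator_backward_batch(d_raw, cache, gen)
            opt_g.step(gen.arrays, grads, 0.1 if fine_tune_active else 1.0)

            if not (np.isfinite(d_loss) and np.isfinite(adv_loss)
                    and np.isfinite(n_total)):
                raise TrainingDivergenceError(epoch)
            d_losses.append(d_loss)
            adv_losses.append(adv_loss)
            neutro_total_epoch += n_total
            gated_epoch += n_gated

        neutro_mean = neutro_total_epoch / (n_items * pixels_per_image)
        adv_mean = float(np.mean(adv_losses))
        record = EpochRecord(
            epoch=epoch,
            disc_loss=float(np.mean(d_losses)),
            gen_adv_loss=adv_mean,
            neutro_total=neutro_total_epoch,
            neutro_mean=neutro_mean,
            gated_count=gated_epoch,
            gen_total_loss=config.adversarial_weight * adv_mean
            + config.neutrosophic_weight * neutro_mean,
            fine_tune=fine_tune_active,
            stop=False,
        )
        history.records.append(record)
        log.info(
            "epoch %d: D=%.4f advG=%.4f neutro=%.6f gated=%d%s",
            epoch, record.disc_loss, record.gen_adv_loss,
            record.neutro_mean, record.gated_count,
            " [fine-tune]" if fine_tune_active else "",
        )
        if neutro_mean < config.fine_tune_threshold:
            fine_tune_active = True
        if should_stop(history, config):
            record.stop = True
            break

    if out_dir is not None:
        _write_run(Path(out_dir), gen, disc, history, config, domain)
    return gen, disc, history


def _write_run(out_dir, gen, disc, history, config, domain):
    out_dir.mkdir(parents=True, exist_ok=True)
    gen_path = out_dir / "generator.npz"
    disc_path = out_dir / "discriminator.npz"
    gen.save(gen_path)
    disc.save(disc_path)
    history.checkpoints = {"generator": str(gen_path), "discriminator": str(disc_path)}
    with open(out_dir / "history.jsonl", "w") as fh:
        for r in history.records:
            fh.write(json.dumps(asdict(r)) + "\n")
    from . import __version__

    final = history.records[-1]
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "pixel_domain": {"max_value": domain.max_value, "channels": domain.channels},
        "epochs_run": len(history.records),
        "final_metrics": {
            "disc_loss": final.disc_loss,
            "gen_adv_loss": final.gen_adv_loss,
            "neutro_mean": final.neutro_mean,
            "gated_count": final.gated_count,
        },
        "checkpoints": history.checkpoints,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _config_dict(config: TrainConfig) -> dict:
    d = asdict(config)
    if math.isinf(d["fine_tune_threshold"]):
        d["fine_tune_threshold"] = "inf"
    return d


def should_stop(history: TrainHistory, config: TrainConfig) -> bool:
    """Patience rule: no relative improvement > 1e-6 for `patience` epochs."""
    losses = history.neutro_means
    if not losses:
        raise PreconditionError("history must contain at least one epoch")
    best = losses[0]
    since = 0
    for loss in losses[1:]:
        if loss < best * (1.0 - 1e-6):
            best, since = loss, 0
        else:
            since += 1
    return since >= config.early_stop_patience


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def impute(gen: ModelParams, image: MaskedImage, seed: int) -> np.ndarray:
    """Fill the missing pixels of one image with the trained generator.

    Observed pixels are bit-identical to the input (pixel-domain
    compositing); the generated values are scaled back to [0, max_value].
    """
    cfg_shape = tuple(gen.config["image_shape"])
    h, w = image.image.shape[:2]
    if (h, w, 1) != cfg_shape and (h, w) != cfg_shape[:2]:
        raise ShapeError(
            f"image shape {image.image.shape} incompatible with generator "
            f"shape {cfg_shape}"
        )
    domain = image.domain
    msk = image.mask.astype(float)
    u_corr = (image.image / domain.max_value) * (1.0 - msk)
    noise = np.random.default_rng(seed).standard_normal(gen.config["noise_dim"])
    raw, _ = generator_forward_batch(
        u_corr[None, ..., None], msk[None], noise[None], gen
    )
    filled = raw[0, ..., 0] * domain.max_value
    return msk * filled + (1.0 - msk) * image.image


def mean_fill(image: MaskedImage) -> np.ndarray:
    """Baseline: fill every missing pixel with the mean observed intensity."""
    msk = image.mask.astype(bool)
    observed = image.image[~msk]
    fill = float(observed.mean()) if observed.size else image.domain.max_value / 2.0
    out = image.image.astype(float).copy()
    out[msk] = fill
    return out


def mode_collapse_diagnostic(
    gen: ModelParams,
    image: MaskedImage,
    n_draws: int = 16,
    epsilon: float = 1e-3,
    seed: int = 0,
):
    """Diversity of imputations across independent noise draws.

    ``diversity`` is the standard deviation across draws of each imputed
    pixel, averaged over the masked region (pixel-domain units);
    ``collapsed`` flags diversity below ``epsilon`` — a generator whose
    output ignores its noise input scores exactly zero.
    Returns ``(collapsed, diversity)``.
    """
    if n_draws < 2:
        raise PreconditionError("n_draws must be >= 2")
    draw_seeds = np.random.SeedSequence(seed).generate_state(n_draws) % (2**31)
    outs = np.stack([impute(gen, image, int(s)) for s in draw_seeds])
    msk = image.mask.astype(bool)
    if not msk.any():
        return True, 0.0
    diversity = float(outs.std(axis=0, ddof=0)[msk].mean())
    return bool(diversity < epsilon), diversity


def zero_noise_weights(gen: ModelParams) -> ModelParams:
    """Copy of a generator whose first FC layer ignores the noise vector."""
    out = gen.copy()
    nd = out.config["noise_dim"]
    out.arrays["fc0_w"][:, -nd:] = 0.0
    return out
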