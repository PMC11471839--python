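# neutrofill

Missing-pixel imputation for grayscale raster images with a small
generative adversarial network whose generator carries an identity (skip)
block, trained under a **neutrosophic 8-connected pixel loss**.

Corrupted rasters — sensor dropouts, occlusions, transmission loss — occur
across biological and medical imaging, remote sensing and vision pipelines.
Filling the holes convincingly requires more than per-pixel regression: the
imputed values must cohere with their spatial neighborhood. `neutrofill`
provides a compact, CPU-friendly, fully seeded implementation of one such
approach, together with synthetic image/mask generators so every component
is testable without external data.

## The model

**Neutrosophic pixel representation.** Each intensity $v \in [0, V]$
(default $V = 255$) maps to a triple of membership degrees

$$T = 1 - \tfrac{v}{V}, \qquad I = \tfrac{v}{V}\left(1 - \tfrac{v}{V}\right), \qquad F = \tfrac{v}{V},$$

so $T + F = 1$ and $I = T \cdot F$ hold exactly per pixel, with the
indeterminacy $I$ maximal ($0.25$) at mid-scale.

**8-connected neighborhood loss.** For every visited pixel the $(T, I, F)$
planes are averaged over its 8-connected neighborhood in the generated and
the reference image. If all three component differences fall strictly below
a threshold $\theta$ (default $0.01$) the pixel is *gated* — considered
reconstructed, contributing zero; otherwise it contributes
$\Delta T^2 + \Delta I^2 + \Delta F^2$. Border handling, neighbor weights,
pixel scope and the aggregation rule are configurable (`LossConfig`).

**Networks.** The generator conditions on the zero-filled corrupted image
plus its mask, runs a 1×1 → 3×3 convolutional stem and one identity block
$x \mapsto \mathrm{conv}_{3\times3}(\mathrm{relu}(\mathrm{conv}_{1\times1}(x))) + x$,
then a fully connected trunk that also receives a noise vector, with a
sigmoid output. Observed pixels pass through unchanged (compositing), so
imputation never alters known content. A fully connected discriminator
scores authenticity. Training alternates discriminator and generator Adam
steps on

$$\mathcal{L}_G = w_{adv}\,\mathrm{BCE}(D(G(x)), 1) + \lambda\, \bar{\mathcal{L}}_{neutro},$$

with threshold-triggered generator-only fine-tuning at a reduced learning
rate, patience-based early stopping on the neutrosophic loss, and a
mode-collapse diagnostic based on imputation diversity across noise draws.

**Metrics.** RMSE, PSNR ($10\log_{10}(V^2/\mathrm{MSE})$), Inception Score
($\exp \mathbb{E}_x\, D_{KL}(p(y|x)\,\|\,p(y))$) and Fréchet distance
($\|\mu_r-\mu_g\|^2 + \mathrm{Tr}(\Sigma_r+\Sigma_g-2(\Sigma_r\Sigma_g)^{1/2})$)
are implemented as pure numerics; IS/FID accept any pluggable classifier or
embedding.

## Worked example

```python
import neutrofill as nf
from neutrofill.metrics import rmse, psnr

dom = nf.PixelDomain(255)
t = nf.to_neutrosophic(64, dom)
print(f"T={t.T:.4f} I={t.I:.4f} F={t.F:.4f}")

ds = nf.make_dataset(200, "gradient", "mcar", (16, 16), seed=0, rate_or_size=0.2)
gen, disc, hist = nf.train(ds, nf.TrainConfig(epochs=100, seed=0))
print(f"epochs run: {len(hist.records)}")
print(f"final mean neutrosophic loss: {hist.records[-1].neutro_mean:.6f}")

held = nf.make_dataset(1, "gradient", "mcar", (16, 16), seed=123, rate_or_size=0.2)[0]
completed = nf.impute(gen, held, seed=0)
print(f"masked-region RMSE: {rmse(completed, held.truth, held.mask == 1):.2f} intensity levels")
print(f"PSNR: {psnr(completed, held.truth, 255):.2f} dB")
collapsed, diversity = nf.mode_collapse_diagnostic(gen, held, n_draws=16)
print(f"mode collapse: {collapsed} (diversity {diversity:.2f})")
```

prints

```
T=0.7490 I=0.1880 F=0.2510
epochs run: 54
final mean neutrosophic loss: 0.000479
masked-region RMSE: 23.72 intensity levels
PSNR: 28.18 dB
mode collapse: False (diversity 2.69)
```

The conversion of intensity 64 shows the membership triple; training on 200
ramp images with 20 % of pixels missing at random stops early once the
neutrosophic loss plateaus; the held-out masked-region RMSE of ~24 levels
is far below the ~74-level mean-fill baseline; and a nonzero diversity
across 16 noise draws indicates the generator has not collapsed to a single
output.

## Command line

```sh
neutrofill simulate --out fixtures --n 8           # image/mask/truth triplets
neutrofill train --data fixtures --out run --epochs 2
neutrofill impute --checkpoint run/generator.npz \
    --image fixtures/image_000.npy --mask fixtures/mask_000.npy --out done.npy
neutrofill evaluate --generated done.npy --actual fixtures/truth_000.npy
neutrofill neutro-table --max 255                  # the full (T, I, F) table
```

Masks use 1 (NPY) / 255 (PNG) for *missing*. Every training run writes a
manifest (config echo, seed, version, final metrics) sufficient to
reproduce it exactly.

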