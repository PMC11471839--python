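# Methods

## Problem setting

Given a grayscale raster with integer intensities in $[0, V]$ and a binary
mask marking missing pixels (missingness assumed independent of the missing
values), the task is to fill the masked region so that the completed image
is both pointwise accurate and spatially coherent with its 8-connected
surroundings. Observed pixels are never altered: the generator's output is
composited as `mask * generated + (1 - mask) * observed` both during
training and at inference, in the pixel domain, so observed values survive
bit-identically.

## Neutrosophic representation and the neighborhood loss

Each intensity $v$ maps to truth / indeterminacy / falsehood memberships
$T = 1 - v/V$, $I = (v/V)(1 - v/V)$, $F = v/V$. The identities $T + F = 1$
and $I = T F$ hold exactly per pixel; after neighborhood averaging $T+F=1$
survives but $I = TF$ does not (Jensen), which is why the loss carries all
three components rather than deriving $I$ from the means.

For every visited pixel, the loss compares the component-wise neighborhood
means of the generated image against the reference. With
$\Delta_c = \bar c_{gen} - \bar c_{real}$ for $c \in \{T, I, F\}$:

* if $|\Delta_T|, |\Delta_I|, |\Delta_F| < \theta$ the pixel is **gated**
  (contributes 0 and is counted in `gated_count`);
* otherwise it contributes $\Delta_T^2 + \Delta_I^2 + \Delta_F^2$.

Configuration choices, with defaults and rationale:

| parameter | default | rationale |
|---|---|---|
| `threshold` θ | 0.01 | ≈ 2.5 intensity levels on the T/F scale at V=255; "close enough" at 8-bit quantization |
| `border_policy` | `valid` | average only in-bounds neighbors; never fabricates intensities (alternatives: `reflect`, `clamp`) |
| `scope` | `all_pixels` | the loss walks every pixel; `masked_only` offered since observed pixels contribute nothing after compositing |
| `aggregation` | `mean_triple_sq` | compare *means first*, then square (3 terms/pixel); `per_element_sq` sums squared neighbor-wise differences instead |
| `weight_kernel` | uniform | a weighted neighborhood average is supported but no canonical weights exist; any non-negative 8-vector summing to 1 is accepted |

The total is reported unnormalized with `evaluated_count` exposed so
callers can normalize; training uses the per-pixel mean. Coordinates are
0-based row-major; the center pixel is excluded from its own neighborhood.

**Gate and gradients.** The gate is a step function and therefore
non-differentiable; during training it is treated as a constant (gradient
zero through gated pixels, straight-through elsewhere). A consequence worth
knowing: once a lone wrong pixel's error drops below roughly
$8 V \theta$ every neighborhood containing it gates and the gradient
vanishes, so the gate threshold bounds the attainable per-pixel accuracy.
Applications needing tight pixel recovery should lower θ (the constant-image
recovery test uses θ = 5·10⁻⁴).

## Networks

Written directly on numpy arrays with explicit forward/backward passes and
an Adam optimizer (lr 2·10⁻⁴, β = (0.5, 0.999)); the nets are small enough
that CPU matmuls dominate and no deep-learning framework is used.

* **Generator** — input: zero-filled corrupted image with the mask stacked
  as a second channel (the mask, not the zero sentinel, is authoritative).
  Stem: 1×1 conv → relu → 3×3 conv (padding 1) → relu, 8 feature channels.
  One identity block `conv3x3(relu(conv1x1(x))) + x` (output channels equal
  input channels so the skip addition is well defined; zero weights make it
  the exact identity, and the skip path contributes a unit Jacobian term so
  gradients always reach the input). Flatten, concatenate a 32-dim standard
  normal noise vector, two FC layers of 256 (relu), FC to H·W, sigmoid.
* **Discriminator** — flatten → two FC layers of 256 with leaky-relu (slope
  0.2) → scalar logit; the public surface reports the sigmoid probability,
  training uses the logit for numerically stable binary cross-entropy.

Checkpoints are single-file NumPy `.npz` archives holding the parameter
arrays plus a JSON metadata entry (kind, architecture config, format
version); save → load round-trips forward outputs bitwise.

## Training loop

Per epoch, over shuffled mini-batches (default 16):

1. generate raw outputs from corrupted inputs + seeded noise; composite;
2. one discriminator Adam step on BCE(real→1, fake→0) — skipped in the
   fine-tuning phase;
3. one generator Adam step on `adversarial_weight · BCE(D(fake), 1) +
   λ · mean neutrosophic loss` (defaults 1 and 10: reconstruction dominates,
   the adversarial term regularizes texture);
4. bookkeeping: epoch record of discriminator loss, generator adversarial
   loss, neutrosophic total/mean and gated count.

**Fine-tuning phase.** When the mean per-pixel neutrosophic loss falls
below `fine_tune_threshold` (default 10⁻³), subsequent epochs update only
the generator at one tenth of the learning rate — a gentler polishing phase
once imputation is already close. An infinite threshold forces the phase
from epoch 1.

**Early stopping.** Training stops when the best neutrosophic loss has not
improved by more than a 10⁻⁶ relative margin for `early_stop_patience`
consecutive epochs (default 10).

**Determinism.** A single master seed feeds `numpy.random.SeedSequence`,
which is spawned into independent streams for generator init, discriminator
init, and the shuffling/noise stream; identical config + dataset reproduce
the history record-for-record. Non-finite losses raise a divergence error
carrying the epoch index.

**Mode-collapse diagnostic.** For one masked image, `n_draws` imputations
under independent noise seeds are compared; diversity is the per-pixel
standard deviation across draws averaged over the masked region (intensity
units). A generator whose noise weights are zeroed scores (numerically)
zero; `collapsed` flags diversity below ε (default 10⁻³, i.e. essentially
noise-invariant output).

## Metrics

* RMSE over an optional mask selection; PSNR as $10\log_{10}(V^2/MSE)$
  with a +∞ sentinel at MSE = 0 (this is the standard orientation in which
  larger is better and typical 8-bit reconstructions land at 20–80 dB).
* Inception Score with natural logarithms, the column-mean marginal, and
  $0\log 0 := 0$; bounded by $[1, K]$.
* Fréchet distance via an eigendecomposition of $\sqrt{\Sigma_r}\,
  \Sigma_g \sqrt{\Sigma_r}$ (symmetric, so the trace of the matrix square
  root is a sum of clipped-at-zero eigenvalue square roots); self-distance
  is 0 to ~10⁻⁸ and tiny negative eigenvalues from roundoff are clipped.
* No pretrained classifier is bundled; IS/FID take any image→probability or
  image→embedding map. The package ships two trivial probes (flattened-pixel
  embeddings; per-image intensity-histogram "classes") that exercise the
  numerics on synthetic data.

## Synthetic data

The generators emulate the study conditions used throughout the tests:
procedural grayscale images (left-to-right ramps spanning the domain,
checkerboards, seeded Gaussian blobs, seeded sinusoids, flat constants) of
default size 16×16, combined with three missingness scenarios — MCAR at
default rate 0.2, three scattered squares of side ⌈min(H,W)/8⌉, and one
centered square of default side H/4. Missing pixels are zero-filled;
ground truth is retained; per-item seeds are spawned from the master seed.

What these fixtures do **not** capture: natural-image statistics (textures,
edges, semantic structure), sensor noise, non-random missingness, and
resolution beyond toy scale. Passing tests demonstrate that the machinery —
losses, gradients, training dynamics, compositing, diagnostics — behaves as
specified, not that the small networks reach state-of-the-art inpainting
quality on real photographs.

## Problem sizes and numerical choices

The scaled-down study (tests and `scripts/acceptance.py`) trains on 200
ramp images of 16×16 with MCAR rate 0.2 for up to 100 epochs and evaluates
on 20 held-out images; the trained model's masked-region RMSE is compared
against the mean-fill baseline (each hole filled with the image's observed
mean). These sizes keep a full run in seconds-to-minutes on one CPU core
while leaving a wide margin between model and baseline.

Other numerics: Glorot-uniform initialization; float64 throughout;
weight-kernel normalization tolerance 10⁻¹²; loss-total/per-pixel-sum
agreement 10⁻⁹; FID tolerance 10⁻⁸; early-stopping improvement margin
10⁻⁶ relative. Equality assertions on noise-ablated diversity allow a
≤10⁻⁹ residue because BLAS summation order is not guaranteed across calls.

## Design choices where the design was open

* The identity block sits once, after the stem — placement and count are
  architectural free parameters; one block suffices at toy scale.
* Noise is injected by concatenation to the flattened conv features before
  the FC trunk (conventional for small conditional GANs).
* An optional discriminator-free mode exists implicitly: setting
  `adversarial_weight = 0` trains on the neutrosophic loss alone; the
  default keeps the adversarial pair.
* `simulate`/`train`/`impute`/`evaluate`/`neutro-table` form the CLI; the
  library functions are the primary interface and the CLI is a thin layer
  over them.

## Known limitations

* Grayscale-first: multi-channel plumbing exists in the configs but the
  toy pipeline and CLI exercise single-channel images.
* The FC trunk ties the checkpoint to one image size; no fully
  convolutional mode.
* The gate bounds per-pixel accuracy at ≈ 8Vθ (see above).
* No GPU or multi-process path; intended scale is tens-of-pixels images.
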