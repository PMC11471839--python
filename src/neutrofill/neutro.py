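"""Neutrosophic pixel representation and the 8-connected neighborhood loss.

Every pixel intensity ``v`` in a domain ``[0, max_value]`` maps to a
neutrosophic triple of membership degrees

    T = 1 - v / max_value        (truth)
    I = (v / max_value) * (1 - v / max_value)   (indeterminacy)
    F = v / max_value            (falsehood)

so that ``T + F = 1`` exactly and ``I = T * F`` per pixel.  The image loss
compares, for each visited pixel, the neutrosophic triples averaged over its
8-connected neighborhood in a generated image against the same statistic in a
reference image.  When all three component differences fall below a threshold
the pixel is considered reconstructed and contributes zero ("gated");
otherwise the squared component differences are accumulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError, PreconditionError, ShapeError

__all__ = [
    "PixelDomain",
    "NeutrosophicTriple",
    "NeighborhoodStats",
    "LossConfig",
    "LossReport",
    "NEIGHBOR_OFFSETS",
    "to_neutrosophic",
    "neutrosophic_table",
    "neighborhood_values",
    "neighborhood_mean_triple",
    "pixel_loss",
    "image_loss",
]

#: 8-connected neighbor offsets in fixed row-major order, center excluded.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)

BorderPolicy = Literal["valid", "reflect", "clamp"]
Scope = Literal["all_pixels", "masked_only"]
Aggregation = Literal["mean_triple_sq", "per_element_sq"]


@dataclass(frozen=True)
class PixelDomain:
    """Integer intensity ceiling and channel count of the pixel space."""

    max_value: int = 255
    channels: int = 1

    def __post_init__(self) -> None:
        if self.max_value < 1:
            raise ConfigurationError(f"max_value must be >= 1, got {self.max_value}")
        if self.channels < 1:
            raise ConfigurationError(f"channels must be >= 1, got {self.channels}")

    def check(self, values: np.ndarray) -> None:
        """Raise :class:`DomainError` if any value falls outside [0, max_value]."""
        arr = np.asarray(values)
        if arr.size == 0:
            return
        lo, hi = float(arr.min()), float(arr.max())
        if lo < 0 or hi > self.max_value:
            offender = lo if lo < 0 else hi
            raise DomainError(
                f"intensity {offender!r} outside pixel domain [0, {self.max_value}]"
            )


@dataclass(frozen=True)
class NeutrosophicTriple:
    """Truth, indeterminacy and falsehood memberships of one intensity."""

    T: float
    I: float
    F: float

    def as_array(self) -> np.ndarray:
        return np.array([self.T, self.I, self.F], dtype=float)


@dataclass(frozen=True)
class NeighborhoodStats:
    """Neutrosophic triple averaged over an 8-connected neighborhood.

    ``T + F = 1`` survives averaging, but ``I = T * F`` holds only per pixel,
    not for the means.
    """

    mean_triple: NeutrosophicTriple
    n_members: int


@dataclass(frozen=True)
class LossConfig:
    """Options of the neighborhood loss.

    threshold
        Per-component gate: a pixel whose three mean-triple differences all
        fall strictly below it contributes zero.  Default 0.01 corresponds to
        roughly 2.5 intensity levels on the T/F scale at ``max_value = 255``.
    border_policy
        ``valid`` averages only in-bounds neighbors (never fabricates
        intensities); ``reflect`` mirrors, ``clamp`` repeats edge pixels.
    scope
        ``all_pixels`` visits every pixel; ``masked_only`` restricts the sum
        to mask-flagged pixels.
    aggregation
        ``mean_triple_sq`` compares the neighborhood *mean* triples (three
        squared terms per pixel); ``per_element_sq`` sums squared triple
        differences over every individual neighbor pair.
    weight_kernel
        Optional 8 non-negative neighbor weights (order of
        :data:`NEIGHBOR_OFFSETS`) summing to 1; ``None`` means uniform.
    """

    threshold: float = 0.01
    border_policy: BorderPolicy = "valid"
    scope: Scope = "all_pixels"
    aggregation: Aggregation = "mean_triple_sq"
    weight_kernel: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ConfigurationError(f"threshold must be >= 0, got {self.threshold}")
        if self.border_policy not in ("valid", "reflect", "clamp"):
            raise ConfigurationError(f"unknown border_policy {self.border_policy!r}")
        if self.scope not in ("all_pixels", "masked_only"):
            raise ConfigurationError(f"unknown scope {self.scope!r}")
        if self.aggregation not in ("mean_triple_sq", "per_element_sq"):
            raise ConfigurationError(f"unknown aggregation {self.aggregation!r}")
        if self.weight_kernel is not None:
            w = np.asarray(self.weight_kernel, dtype=float)
            if w.shape != (8,):
                raise ConfigurationError("weight_kernel must have exactly 8 entries")
            if (w < 0).any():
                raise ConfigurationError("weight_kernel entries must be non-negative")
            if abs(float(w.sum()) - 1.0) > 1e-12:
                raise ConfigurationError("weight_kernel must sum to 1 within 1e-12")
            object.__setattr__(self, "weight_kernel", tuple(float(x) for x in w))


@dataclass
class LossReport:
    """Result of one image-loss evaluation."""

    total: float
    per_pixel: np.ndarray
    gated_count: int
    evaluated_count: int
    config: LossConfig = field(default_factory=LossConfig)


def to_neutrosophic(value: float, domain: PixelDomain) -> NeutrosophicTriple:
    """Convert one intensity into its neutrosophic (T, I, F) triple."""
    if domain.max_value < 1:
        raise ConfigurationError("max_value must be positive")
    if not (0 <= value <= domain.max_value):
        raise DomainError(
            f"intensity {value!r} outside pixel domain [0, {domain.max_value}]"
        )
    f = float(value) / float(domain.max_value)
    return NeutrosophicTriple(T=1.0 - f, I=f * (1.0 - f), F=f)


def neutrosophic_table(domain: PixelDomain) -> list[NeutrosophicTriple]:
    """The full intensity-to-triple table, indexed by intensity 0..max_value."""
    return [to_neutrosophic(v, domain) for v in range(domain.max_value + 1)]


def _neighbor_coords(
    row: int, col: int, h: int, w: int, policy: BorderPolicy
) -> list[tuple[int, int]]:
    coords = []
    for dr, dc in NEIGHBOR_OFFSETS:
        r, c = row + dr, col + dc
        if policy == "valid":
            if 0 <= r < h and 0 <= c < w:
                coords.append((r, c))
        elif policy == "clamp":
            coords.append((min(max(r, 0), h - 1), min(max(c, 0), w - 1)))
        elif policy == "reflect":
            coords.append((_reflect(r, h), _reflect(c, w)))
        else:  # pragma: no cover - guarded by LossConfig
            raise ConfigurationError(f"unknown border_policy {policy!r}")
    return coords


def _reflect(i: int, n: int) -> int:
    # reflect-without-repeat (scipy 'mirror'): -1 -> 1, n -> n-2
    if n == 1:
        return 0
    while i < 0 or i >= n:
        if i < 0:
            i = -i
        if i >= n:
            i = 2 * (n - 1) - i
    return i


def neighborhood_values(
    image: np.ndarray, row: int, col: int, policy: BorderPolicy = "valid"
) -> list[float]:
    """Intensities of the 8-connected neighbors of ``(row, col)``.

    Under ``valid`` only in-bounds neighbors are returned (3 at a corner, 5 on
    an edge, 8 in the interior); under ``reflect``/``clamp`` exactly 8 values
    are returned.  The center pixel is excluded.
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    if not (0 <= row < h and 0 <= col < w):
        raise IndexError(f"pixel ({row}, {col}) outside image of shape {img.shape}")
    return [float(img[r, c]) for r, c in _neighbor_coords(row, col, h, w, policy)]


def neighborhood_mean_triple(
    values: Sequence[float],
    domain: PixelDomain,
    weights: Optional[Sequence[float]] = None,
) -> NeighborhoodStats:
    """(Weighted) mean neutrosophic triple of a list of neighbor intensities."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise PreconditionError("neighborhood must contain at least one value")
    domain.check(vals)
    f = vals / float(domain.max_value)
    t, i = 1.0 - f, f * (1.0 - f)
    if weights is None:
        w = np.full(vals.size, 1.0 / vals.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != vals.shape:
            raise ConfigurationError(
                f"weights length {w.size} does not match {vals.size} values"
            )
        w = w / w.sum()
    triple = NeutrosophicTriple(
        T=float(w @ t), I=float(w @ i), F=float(w @ f)
    )
    return NeighborhoodStats(mean_triple=triple, n_members=int(vals.size))


def pixel_loss(
    gen_stats: NeighborhoodStats,
    real_stats: NeighborhoodStats,
    threshold: float,
) -> float:
    """Threshold-gated squared difference of two neighborhood mean triples.

    Returns 0 when |dT|, |dI| and |dF| are all strictly below the threshold
    (the pixel is "sufficiently close"); otherwise dT**2 + dI**2 + dF**2.
    """
    if threshold < 0:
        raise ConfigurationError(f"threshold must be >= 0, got {threshold}")
    d = gen_stats.mean_triple.as_array() - real_stats.mean_triple.as_array()
    if np.all(np.abs(d) < threshold):
        return 0.0
    return float(np.dot(d, d))


# ---------------------------------------------------------------------------
# Vectorized image loss
# ---------------------------------------------------------------------------


def _shift(arr: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """arr shifted so that out[r, c] = arr[r + dr, c + dc], zero outside."""
    h, w = arr.shape
    out = np.zeros_like(arr)
    rs = slice(max(dr, 0), h + min(dr, 0))
    cs = slice(max(dc, 0), w + min(dc, 0))
    rd = slice(max(-dr, 0), h + min(-dr, 0))
    cd = slice(max(-dc, 0), w + min(-dc, 0))
    out[rd, cd] = arr[rs, cs]
    return out


def neighbor_mean_maps(
    comps: np.ndarray, policy: BorderPolicy, weights: Optional[np.ndarray] = None
) -> np.ndarray:
    """Per-pixel neighborhood means of component planes.

    ``comps`` has shape (K, H, W); the result has the same shape, where entry
    (k, r, c) is the (weighted) mean of plane k over the 8-connected
    neighborhood of (r, c) under the given border policy.
    """
    k, h, w = comps.shape
    if policy in ("reflect", "clamp"):
        mode = "reflect" if policy == "reflect" else "edge"
        padded = np.pad(comps, ((0, 0), (1, 1), (1, 1)), mode=mode)
    else:
        padded = None
    if weights is None:
        wts = np.full(8, 1.0, dtype=float)
    else:
        wts = np.asarray(weights, dtype=float)
    num = np.zeros_like(comps, dtype=float)
    den = np.zeros((h, w), dtype=float)
    for wt, (dr, dc) in zip(wts, NEIGHBOR_OFFSETS):
        if padded is not None:
            sh = padded[:, 1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
            num += wt * sh
            den += wt
        else:
            for ki in range(k):
                num[ki] += wt * _shift(comps[ki], dr, dc)
            ones = _shift(np.ones((h, w)), dr, dc)
            den += wt * ones
    return num / den[None, :, :]


def _components(norm: np.ndarray) -> np.ndarray:
    """Stack (T, I, F) planes of a normalized intensity grid."""
    return np.stack([1.0 - norm, norm * (1.0 - norm), norm])


def image_loss(
    generated: np.ndarray,
    real: np.ndarray,
    mask: Optional[np.ndarray] = None,
    config: LossConfig = LossConfig(),
    domain: PixelDomain = PixelDomain(),
) -> LossReport:
    """Total threshold-gated neutrosophic neighborhood loss of an image pair.

    Visits every pixel (``scope='all_pixels'``) or only mask-flagged ones,
    compares the neutrosophic statistics of the 8-connected neighborhood of
    each visited pixel in ``generated`` against ``real``, gates pixels whose
    mean-triple differences all fall below the threshold, and sums the rest.
    Deterministic in its inputs.
    """
    gen = np.asarray(generated, dtype=float)
    ref = np.asarray(real, dtype=float)
    if gen.shape != ref.shape:
        raise ShapeError(f"image shapes differ: {gen.shape} vs {ref.shape}")
    if gen.ndim != 2:
        raise ShapeError(f"expected a 2-D intensity grid, got shape {gen.shape}")
    if mask is not None:
        m = np.asarray(mask)
        if m.shape != gen.shape:
            raise ShapeError(f"mask shape {m.shape} differs from image {gen.shape}")
    elif config.scope == "masked_only":
        raise ConfigurationError("scope='masked_only' requires a mask")
    else:
        m = None
    domain.check(gen)
    domain.check(ref)

    wts = np.asarray(config.weight_kernel, dtype=float) if config.weight_kernel else None
    cg = _components(gen / domain.max_value)
    cr = _components(ref / domain.max_value)
    mg = neighbor_mean_maps(cg, config.border_policy, wts)
    mr = neighbor_mean_maps(cr, config.border_policy, wts)
    diff = mg - mr  # (3, H, W)
    gate = np.all(np.abs(diff) < config.threshold, axis=0)

    if config.aggregation == "mean_triple_sq":
        contrib = np.sum(diff * diff, axis=0)
    else:
        # squared differences of every individual neighbor triple
        per = np.zeros(gen.shape, dtype=float)
        h, w = gen.shape
        if config.border_policy in ("reflect", "clamp"):
            mode = "reflect" if config.border_policy == "reflect" else "edge"
            pg = np.pad(cg, ((0, 0), (1, 1), (1, 1)), mode=mode)
            pr = np.pad(cr, ((0, 0), (1, 1), (1, 1)), mode=mode)
            for dr, dc in NEIGHBOR_OFFSETS:
                d = (
                    pg[:, 1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
                    - pr[:, 1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
                )
                per += np.sum(d * d, axis=0)
        else:
            dc3 = cg - cr
            for dr, dcc in NEIGHBOR_OFFSETS:
                for ki in range(3):
                    per += _shift(dc3[ki], dr, dcc) ** 2
        contrib = per

    visited = np.ones(gen.shape, dtype=bool)
    if config.scope == "masked_only":
        visited = np.asarray(m, dtype=bool)

    per_pixel = np.where(visited & ~gate, contrib, 0.0)
    gated_count = int(np.count_nonzero(visited & gate))
    return LossReport(
        total=float(per_pixel.sum()),
        per_pixel=per_pixel,
        gated_count=gated_count,
        evaluated_count=int(np.count_nonzero(visited)),
        config=config,
    )
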