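"""Seeded toy images and missingness masks.

Stand-ins for real corrupted images: procedurally generated grayscale
rasters (gradients, checkerboards, Gaussian blobs, sinusoids, constants)
combined with the three classic missingness scenarios — pixels missing
completely at random, several small square holes, and a single centered
square.  Missing pixels are zero-filled ("black dots"); the mask, not the
sentinel value, is authoritative.  Every generator is a pure function of its
arguments, the seed included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, PreconditionError, ValidationError
from .neutro import PixelDomain

__all__ = ["MaskedImage", "make_image", "make_mask", "make_dataset"]

IMAGE_KINDS = ("gradient", "checkerboard", "blobs", "sinusoid", "constant")
MASK_PATTERNS = ("mcar", "squares", "central_square")


@dataclass
class MaskedImage:
    """A raster paired with its binary missingness mask (1 = missing)."""

    image: np.ndarray
    mask: np.ndarray
    truth: Optional[np.ndarray] = None
    domain: PixelDomain = PixelDomain()

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.mask.shape != self.image.shape[:2]:
            raise ValidationError(
                f"mask shape {self.mask.shape} != image {self.image.shape[:2]}"
            )
        if not np.isin(self.mask, (0, 1)).all():
            raise ValidationError("mask entries must be 0 or 1")
        self.mask = self.mask.astype(np.uint8)
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=float)
            if self.truth.shape != self.image.shape:
                raise ValidationError(
                    f"truth shape {self.truth.shape} != image {self.image.shape}"
                )
            obs = self.mask == 0
            if not np.array_equal(self.image[obs], self.truth[obs]):
                raise ValidationError("observed pixels must match the ground truth")
        self.domain.check(self.image)


def make_image(
    kind: str,
    height: int,
    width: int,
    seed: int = 0,
    domain: PixelDomain = PixelDomain(),
    cell_size: Optional[int] = None,
) -> np.ndarray:
    """One procedural grayscale image with integer intensities.

    ``gradient`` is a left-to-right ramp spanning the domain (pixel value v
    at column v for a 1x256 image); ``checkerboard`` alternates 0 and
    max_value in square cells; ``blobs`` sums seeded Gaussian bumps;
    ``sinusoid`` is a seeded 2-D sine pattern; ``constant`` is a seeded flat
    level.  Deterministic for fixed arguments.
    """
    if height < 1 or width < 1:
        raise ConfigurationError("height and width must be positive")
    if kind not in IMAGE_KINDS:
        raise ConfigurationError(
            f"unknown image kind {kind!r}; expected one of {IMAGE_KINDS}"
        )
    rng = np.random.default_rng(seed)
    mv = domain.max_value
    h, w = height, width
    if kind == "gradient":
        col = np.arange(w) * (mv / (w - 1)) if w > 1 else np.zeros(1)
        img = np.tile(col, (h, 1))
    elif kind == "checkerboard":
        cell = cell_size or max(1, min(h, w) // 4)
        rr, cc = np.indices((h, w))
        img = (((rr // cell) + (cc // cell)) % 2) * mv
    elif kind == "blobs":
        n_blobs = int(rng.integers(2, 5))
        rr, cc = np.indices((h, w))
        img = np.zeros((h, w))
        for _ in range(n_blobs):
            r0, c0 = rng.uniform(0, h), rng.uniform(0, w)
            sig = rng.uniform(min(h, w) / 8, min(h, w) / 3)
            img += np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sig**2))
        img = img / img.max() * mv
    elif kind == "sinusoid":
        fr = rng.uniform(0.5, 2.0, size=2)
        ph = rng.uniform(0, 2 * np.pi, size=2)
        rr, cc = np.indices((h, w))
        s = np.sin(2 * np.pi * fr[0] * rr / h + ph[0]) * np.sin(
            2 * np.pi * fr[1] * cc / w + ph[1]
        )
        img = (s + 1.0) / 2.0 * mv
    else:  # constant
        img = np.full((h, w), float(rng.integers(0, mv + 1)))
    return np.rint(img).astype(float)


def make_mask(
    pattern: str,
    height: int,
    width: int,
    rate_or_size: Optional[float] = None,
    seed: int = 0,
) -> np.ndarray:
    """One binary missingness mask (1 = missing).

    ``mcar`` flags each pixel independently with the given rate (default
    0.2); ``squares`` drops 3 seeded square holes of side
    ``ceil(min(H, W) / 8)`` (overlap allowed); ``central_square`` drops one
    centered square whose side is ``rate_or_size`` pixels (values below 1
    are read as a fraction of the smaller image side; default H/4).
    """
    if pattern not in MASK_PATTERNS:
        raise ConfigurationError(
            f"unknown mask pattern {pattern!r}; expected one of {MASK_PATTERNS}"
        )
    rng = np.random.default_rng(seed)
    h, w = height, width
    mask = np.zeros((h, w), dtype=np.uint8)
    if pattern == "mcar":
        rate = 0.2 if rate_or_size is None else float(rate_or_size)
        if not (0.0 < rate < 1.0):
            raise ConfigurationError(f"mcar rate must be in (0, 1), got {rate}")
        mask = (rng.random((h, w)) < rate).astype(np.uint8)
    elif pattern == "squares":
        side = (
            math.ceil(min(h, w) / 8)
            if rate_or_size is None
            else _square_side(rate_or_size, h, w)
        )
        for _ in range(3):
            r0 = int(rng.integers(0, h - side + 1))
            c0 = int(rng.integers(0, w - side + 1))
            mask[r0 : r0 + side, c0 : c0 + side] = 1
    else:  # central_square
        side = (
            max(1, h // 4)
            if rate_or_size is None
            else _square_side(rate_or_size, h, w)
        )
        r0, c0 = (h - side) // 2, (w - side) // 2
        mask[r0 : r0 + side, c0 : c0 + side] = 1
    return mask


def _square_side(value: float, h: int, w: int) -> int:
    side = int(round(value * min(h, w))) if value < 1 else int(value)
    if not (1 <= side < min(h, w)):
        raise ConfigurationError(
            f"square side {side} must lie in [1, {min(h, w) - 1})"
        )
    return side


def make_dataset(
    n: int,
    image_kind: str = "gradient",
    mask_pattern: str = "mcar",
    size: tuple[int, int] = (16, 16),
    seed: int = 0,
    rate_or_size: Optional[float] = None,
    domain: PixelDomain = PixelDomain(),
) -> list[MaskedImage]:
    """``n`` corrupted images with ground truth retained.

    Per-item seeds are spawned deterministically from the master seed;
    masked pixels are zero-filled in ``image`` while ``truth`` keeps the
    uncorrupted values.
    """
    if n < 1:
        raise PreconditionError(f"n must be >= 1, got {n}")
    h, w = size
    children = np.random.SeedSequence(seed).spawn(n)
    items = []
    for child in children:
        s_img, s_mask = (int(x) % (2**31) for x in child.generate_state(2))
        truth = make_image(image_kind, h, w, seed=s_img, domain=domain)
        mask = make_mask(mask_pattern, h, w, rate_or_size, seed=s_mask)
        corrupted = truth * (1 - mask)
        items.append(MaskedImage(image=corrupted, mask=mask, truth=truth,
                                 domain=domain))
    return items
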