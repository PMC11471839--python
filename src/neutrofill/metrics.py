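"""Reconstruction and generation-quality metrics.

Pure numerics over pixel grids, class-probability matrices and Gaussian
moment summaries:

* RMSE over an optional mask selection,
* PSNR in the standard orientation ``10 * log10(MAX^2 / MSE)``,
* Inception Score ``exp(E_x KL(p(y|x) || p(y)))`` with the column-mean
  marginal and natural logarithms,
* Frechet distance ``||mu_r - mu_g||^2 + Tr(S_r + S_g - 2 (S_r S_g)^{1/2})``
  computed through an eigendecomposition of the symmetrized product with
  tiny negative eigenvalues clipped to zero.

No pretrained classifier is bundled: IS and FID accept any pluggable map
from images to class probabilities or feature embeddings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg

from .errors import PreconditionError, ShapeError, ValidationError

__all__ = [
    "ClassProbabilityMatrix",
    "GaussianMoments",
    "rmse",
    "psnr",
    "inception_score",
    "fid",
    "moments_from_embeddings",
    "write_metrics_report",
]


def _validate_probs(probs: np.ndarray) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.ndim != 2:
        raise ValidationError("probability matrix must be 2-D (samples x classes)")
    if (p < 0).any():
        raise ValidationError("probabilities must be non-negative")
    rows = p.sum(axis=1)
    bad = np.abs(rows - 1.0) > 1e-9
    if bad.any():
        raise ValidationError(
            f"rows {np.nonzero(bad)[0].tolist()} do not sum to 1 within 1e-9"
        )
    return p


@dataclass(frozen=True)
class ClassProbabilityMatrix:
    """Per-sample class conditionals p(y|x); rows sum to 1."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", _validate_probs(self.probs))


@dataclass(frozen=True)
class GaussianMoments:
    """Mean vector and (numerically) PSD covariance of an embedding cloud."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if cov.shape != (mean.size, mean.size):
            raise ShapeError(f"cov shape {cov.shape} != ({mean.size}, {mean.size})")
        if np.abs(cov - cov.T).max() > 1e-9:
            raise ValidationError("covariance must be symmetric within 1e-9")
        if scipy.linalg.eigvalsh(cov).min() < -1e-8:
            raise ValidationError("covariance must be PSD within 1e-8")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)


def rmse(
    generated: np.ndarray,
    actual: np.ndarray,
    mask: Optional[np.ndarray] = None,
) -> float:
    """Root mean squared difference over the (optionally masked) entries."""
    g = np.asarray(generated, dtype=float)
    a = np.asarray(actual, dtype=float)
    if g.shape != a.shape:
        raise ShapeError(f"shapes differ: {g.shape} vs {a.shape}")
    d = g - a
    if mask is not None:
        sel = np.asarray(mask, dtype=bool)
        if sel.shape != g.shape:
            raise ShapeError(f"mask shape {sel.shape} != {g.shape}")
        d = d[sel]
    if d.size == 0:
        raise PreconditionError("rmse selection is empty")
    return float(np.sqrt(np.mean(d * d)))


def psnr(generated: np.ndarray, actual: np.ndarray, max_value: float) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images are identical."""
    if max_value <= 0:
        raise PreconditionError(f"max_value must be > 0, got {max_value}")
    g = np.asarray(generated, dtype=float)
    a = np.asarray(actual, dtype=float)
    if g.shape != a.shape:
        raise ShapeError(f"shapes differ: {g.shape} vs {a.shape}")
    mse = float(np.mean((g - a) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(max_value**2 / mse)


def inception_score(probs) -> float:
    """exp of the mean KL divergence of p(y|x) from the marginal p(y).

    1 for indistinguishable conditionals, up to K for confident and
    perfectly balanced one-hot rows over K classes.  0 * log 0 := 0.
    """
    p = probs.probs if isinstance(probs, ClassProbabilityMatrix) else _validate_probs(probs)
    marginal = p.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * (np.log(p) - np.log(marginal)), 0.0)
    return float(np.exp(terms.sum(axis=1).mean()))


def _psd_sqrt_trace(a: np.ndarray, b: np.ndarray) -> float:
    """Tr((a b)^{1/2}) for PSD a, b via sqrt(a) b sqrt(a) symmetrization."""
    wa, va = scipy.linalg.eigh(a)
    wa = np.clip(wa, 0.0, None)
    sa = (va * np.sqrt(wa)) @ va.T
    w = scipy.linalg.eigvalsh(sa @ b @ sa)
    return float(np.sqrt(np.clip(w, 0.0, None)).sum())


def fid(real: GaussianMoments, gen: GaussianMoments) -> float:
    """Frechet distance between two Gaussian moment summaries."""
    if real.mean.size != gen.mean.size:
        raise ShapeError(
            f"dimension mismatch: {real.mean.size} vs {gen.mean.size}"
        )
    dmu = real.mean - gen.mean
    trace = float(np.trace(real.cov) + np.trace(gen.cov)) - 2.0 * _psd_sqrt_trace(
        real.cov, gen.cov
    )
    return max(float(dmu @ dmu) + trace, 0.0)


def moments_from_embeddings(embeddings: np.ndarray) -> GaussianMoments:
    """Sample mean and unbiased sample covariance of an embedding matrix."""
    e = np.atleast_2d(np.asarray(embeddings, dtype=float))
    if e.shape[0] < 2:
        raise PreconditionError("at least 2 samples are required")
    mean = e.mean(axis=0)
    cov = np.cov(e, rowvar=False, ddof=1)
    return GaussianMoments(mean=mean, cov=np.atleast_2d(cov))


def pixel_embeddings(images: np.ndarray) -> np.ndarray:
    """Flattened-pixel feature map: (N, H, W[, C]) -> (N, H*W*C).

    The simplest pluggable embedding for the Frechet distance; any callable
    producing one feature row per image can replace it.
    """
    arr = np.asarray(images, dtype=float)
    return arr.reshape(arr.shape[0], -1)


def intensity_histogram_probs(
    images: np.ndarray, n_bins: int = 16, max_value: float = 255.0
) -> np.ndarray:
    """Normalized per-image intensity histograms as class conditionals.

    A trivial pluggable "classifier" for the Inception Score on synthetic
    data: each image's distribution over ``n_bins`` intensity bands plays
    the role of p(y|x); rows sum to 1 by construction.
    """
    arr = np.asarray(images, dtype=float)
    n = arr.shape[0]
    flat = arr.reshape(n, -1)
    bins = np.linspace(0.0, max_value, n_bins + 1)
    idx = np.clip(np.digitize(flat, bins[1:-1]), 0, n_bins - 1)
    probs = np.zeros((n, n_bins))
    for i in range(n):
        counts = np.bincount(idx[i], minlength=n_bins)
        probs[i] = counts / counts.sum()
    return probs


def write_metrics_report(metrics: dict, path_text, path_json=None) -> None:
    """Flat key/value report, human-readable plus optional JSON mirror."""
    with open(path_text, "w") as fh:
        for key, value in metrics.items():
            fh.write(f"{key}\t{value}\n")
    if path_json is not None:
        with open(path_json, "w") as fh:
            json.dump({k: (None if isinstance(v, float) and not np.isfinite(v)
                           else v) for k, v in metrics.items()}, fh, indent=2)
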