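"""Readers and writers for images and masks (PNG, TIFF, NPY).

Images live in an integer pixel domain [0, max_value]; masks are strictly
binary (PNG 0/255 or boolean/0-1 NPY) with 1 or 255 meaning *missing*.
16-bit rasters are rescaled into the domain and the applied scaling is
logged; float NPY grids in [0, 1] are scaled by max_value.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .errors import DomainError, FormatError, ValidationError
from .neutro import PixelDomain

__all__ = ["read_image", "read_mask", "write_image", "write_mask"]

log = logging.getLogger("neutrofill.io")

_LUMA = np.array([0.299, 0.587, 0.114])


def _load_raster(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    try:
        if suffix == ".npy":
            return np.load(path)
        if suffix in (".tif", ".tiff"):
            import tifffile

            return tifffile.imread(path)
        if suffix == ".png":
            import imageio.v3 as iio

            return iio.imread(path)
    except FileNotFoundError:
        raise FormatError(f"file not found: {path}") from None
    except Exception as exc:  # unreadable content
        raise FormatError(f"could not read {path}: {exc}") from exc
    raise FormatError(f"unsupported format {suffix!r} for {path} "
                      "(expected .png, .tif/.tiff or .npy)")


def read_image(path, expected_domain: PixelDomain = PixelDomain()) -> np.ndarray:
    """Load an intensity grid and bring it into the expected pixel domain."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    raw = _load_raster(path)
    arr = raw.astype(float)
    if arr.ndim == 3 and expected_domain.channels == 1:
        arr = arr[:, :, :3] @ _LUMA
        log.info("converted RGB input %s to luminance", path)
    if raw.dtype == np.uint16:
        scale = expected_domain.max_value / 65535.0
        arr = arr * scale
        log.info("rescaled 16-bit input %s by %g", path, scale)
    elif path.suffix.lower() == ".npy" and np.issubdtype(raw.dtype, np.floating):
        if arr.size and 0.0 <= arr.min() and arr.max() <= 1.0 and \
                expected_domain.max_value > 1:
            arr = arr * expected_domain.max_value
            log.info("scaled [0,1] float NPY %s by %d", path,
                     expected_domain.max_value)
    if arr.size and (arr.min() < 0 or arr.max() > expected_domain.max_value):
        raise DomainError(
            f"{path}: values [{arr.min():g}, {arr.max():g}] outside "
            f"[0, {expected_domain.max_value}]"
        )
    return arr


def read_mask(path) -> np.ndarray:
    """Load a strictly binary mask as a 0/1 uint8 grid (1 = missing).

    PNG masks must contain only {0, 255}; NPY masks must be boolean or
    contain only {0, 1}.  Anything else is an error, never a threshold.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    arr = _load_raster(path)
    if path.suffix.lower() == ".png":
        if arr.ndim == 3:
            arr = arr[:, :, 0]
        offending = np.setdiff1d(np.unique(arr), [0, 255])
        if offending.size:
            raise ValidationError(
                f"{path}: mask contains values other than 0/255: "
                f"{offending.tolist()[:10]}"
            )
        return (arr == 255).astype(np.uint8)
    if arr.dtype == bool:
        return arr.astype(np.uint8)
    offending = np.setdiff1d(np.unique(arr), [0, 1])
    if offending.size:
        raise ValidationError(
            f"{path}: mask contains values other than 0/1: "
            f"{offending.tolist()[:10]}"
        )
    return arr.astype(np.uint8)


def write_image(path, grid: np.ndarray,
                domain: PixelDomain = PixelDomain()) -> None:
    """Write a grid as 8-bit PNG, TIFF, or exact NPY depending on suffix."""
    path = Path(path)
    arr = np.asarray(grid, dtype=float)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        np.save(path, arr)
        return
    quant = np.rint(np.clip(arr / domain.max_value, 0, 1) * 255).astype(np.uint8)
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, quant)
    elif suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, quant)
    else:
        raise FormatError(f"unsupported output format {suffix!r}")


def write_mask(path, mask: np.ndarray) -> None:
    """Write a 0/1 mask as 0/255 PNG or boolean NPY."""
    path = Path(path)
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise ValidationError("mask entries must be 0 or 1")
    if path.suffix.lower() == ".npy":
        np.save(path, m.astype(bool))
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, (m * 255).astype(np.uint8))
    else:
        raise FormatError(f"unsupported mask format {path.suffix!r}")
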