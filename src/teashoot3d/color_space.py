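"""Image I/O and RGB/HSI color conversion.

Tea-shoot segmentation works in the hue-saturation plane because the color
difference between tender shoots (light yellow-green) and mature leaves
(dark green) is mostly a hue shift that is robust to brightness variation.
This module provides the conversion between RGB rasters in ``[0, 1]`` and
the geometric (arccos-based) HSI space, plus PNG/JPEG/TIFF readers and
writers used by the pipeline.

Conventions
-----------
* RGB images are ``float64`` arrays of shape ``(height, width, 3)`` with
  channel values in ``[0, 1]``.
* HSI images have the same shape; channel 0 is hue in degrees ``[0, 360)``,
  channel 1 saturation in ``[0, 1]``, channel 2 intensity in ``[0, 1]``.
* Achromatic pixels (``R == G == B``, including black) get ``H = 0`` and
  ``S = 0`` by convention so every pixel has a defined, reproducible color
  vector.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

__all__ = [
    "read_image",
    "write_image",
    "write_label_map",
    "read_label_map",
    "rgb_to_hsi",
    "hsi_to_rgb",
    "circular_hue_diff",
]


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/JPEG/TIFF image as an RGB float array in ``[0, 1]``.

    Grayscale images are broadcast to three channels; an alpha channel, if
    present, is dropped.

    Raises
    ------
    IOError
        If the file is missing or cannot be decoded; the message names the
        offending path.
    """
    try:
        raw = iio.imread(path)
    except Exception as exc:  # pragma: no cover - message formatting only
        raise IOError(f"cannot read image file {path!r}: {exc}") from exc
    arr = np.asarray(raw)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    out = arr.astype(np.float64)
    return np.clip(out, 0.0, 1.0)


def write_image(path: str | os.PathLike, rgb: np.ndarray) -> None:
    """Write an RGB float array in ``[0, 1]`` as an 8-bit image file."""
    arr = np.clip(np.asarray(rgb, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(path, np.round(arr * 255.0).astype(np.uint8))


def write_label_map(path: str | os.PathLike, labels: np.ndarray) -> None:
    """Write an integer label map as a 16-bit single-channel PNG."""
    lab = np.asarray(labels)
    if lab.min() < 0 or lab.max() > 65535:
        raise ValueError("label ids must fit in uint16 for PNG export")
    iio.imwrite(path, lab.astype(np.uint16))


def read_label_map(path: str | os.PathLike) -> np.ndarray:
    """Read a 16-bit PNG label map back as an integer array."""
    return np.asarray(iio.imread(path)).astype(np.int64)


def rgb_to_hsi(rgb: np.ndarray) -> np.ndarray:
    """Convert an RGB image in ``[0, 1]`` to geometric HSI.

    Uses the standard arccos formulation::

        I = (R + G + B) / 3
        S = 1 - min(R, G, B) / I          (0 where I == 0)
        H = arccos( ((R-G) + (R-B)) / 2 / sqrt((R-G)^2 + (R-B)(G-B)) )

    with ``H -> 360 - H`` when ``B > G``, hue reported in degrees.
    Achromatic pixels get ``H = 0, S = 0``.
    """
    arr = np.asarray(rgb, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    i = (r + g + b) / 3.0
    mn = np.minimum(np.minimum(r, g), b)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(i > 0, 1.0 - mn / np.where(i > 0, i, 1.0), 0.0)
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    achromatic = den < 1e-12
    cosang = np.clip(num / np.where(achromatic, 1.0, den), -1.0, 1.0)
    h = np.degrees(np.arccos(cosang))
    h = np.where(b > g, 360.0 - h, h)
    h = np.where(achromatic, 0.0, h)
    s = np.where(achromatic, s, s)  # keep S from the min/I formula
    s = np.clip(s, 0.0, 1.0)
    out = np.stack([h % 360.0, s, i], axis=-1)
    return out


def hsi_to_rgb(hsi: np.ndarray) -> np.ndarray:
    """Invert :func:`rgb_to_hsi` (sector-wise inverse of the arccos form).

    Input hue is in degrees; output RGB is clipped to ``[0, 1]``.  For
    saturations attainable at the given intensity the round trip
    ``hsi_to_rgb(rgb_to_hsi(x))`` reproduces ``x`` to floating precision.
    """
    arr = np.asarray(hsi, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) HSI array")
    h = arr[..., 0] % 360.0
    s = np.clip(arr[..., 1], 0.0, 1.0)
    i = np.clip(arr[..., 2], 0.0, 1.0)

    # Work sector-by-sector; within each 120-degree sector one channel is
    # I(1-S), one follows the cosine ratio, the third closes the sum 3I.
    h_sector = h.copy()
    sector = np.zeros(h.shape, dtype=np.int8)
    sector[(h >= 120.0) & (h < 240.0)] = 1
    sector[h >= 240.0] = 2
    h_sector = h - 120.0 * sector

    hr = np.radians(h_sector)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.cos(hr) / np.cos(np.radians(60.0) - hr)
    c1 = i * (1.0 - s)
    c2 = i * (1.0 + s * ratio)
    c3 = 3.0 * i - (c1 + c2)

    r = np.where(sector == 0, c2, np.where(sector == 1, c1, c3))
    g = np.where(sector == 0, c3, np.where(sector == 1, c2, c1))
    b = np.where(sector == 0, c1, np.where(sector == 1, c3, c2))
    rgb = np.stack([r, g, b], axis=-1)
    return np.clip(rgb, 0.0, 1.0)


def circular_hue_diff(h1: np.ndarray | float, h2: np.ndarray | float) -> np.ndarray | float:
    """Minimal angular difference between hues in degrees, in ``[0, 180]``."""
    d = np.abs(np.asarray(h1, dtype=np.float64) - np.asarray(h2, dtype=np.float64)) % 360.0
    return np.minimum(d, 360.0 - d)
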