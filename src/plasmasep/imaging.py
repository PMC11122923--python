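"""Plasma volume from reservoir images: segment, measure area, apply V = S*h.

The bench protocol photographs the reservoir groove every 30 s; because the
groove height ``h`` is constant, the plasma volume is simply the wetted
area times the height.  This module replaces the manual ImageJ measurement
with thresholding (fixed or Otsu) on 8-bit greyscale frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .estimation import FiltrationCurve

__all__ = [
    "PlasmaMask",
    "ReservoirImage",
    "segment_plasma",
    "plasma_area",
    "volume_from_area",
    "curve_from_images",
]


@dataclass
class ReservoirImage:
    """8-bit greyscale frame of the reservoir with its physical pixel size
    (um per pixel edge) and an optional acquisition timestamp in seconds."""

    image: np.ndarray
    pixel_size: float
    timestamp: float | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2 or self.image.size == 0:
            raise ValueError("image must be a nonempty 2-D array")
        if self.image.min() < 0 or self.image.max() > 255:
            raise ValueError("image intensities must lie in [0, 255]")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel size must be positive, got {self.pixel_size}")


@dataclass
class PlasmaMask:
    """Binary plasma mask (True = plasma) with its pixel size in um."""

    mask: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or self.mask.size == 0:
            raise ValueError("mask must be a nonempty 2-D array")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel size must be positive, got {self.pixel_size}")


def segment_plasma(
    img: ReservoirImage, threshold: float | str = "auto", invert: bool = False
) -> PlasmaMask:
    """Threshold an image into a plasma mask.

    Plasma is assumed bright on a dark background (set ``invert=True`` for
    the opposite polarity).  ``threshold`` is either a fixed intensity —
    pixels at or above it are plasma — or ``"auto"`` for Otsu's bimodal
    histogram split.  A perfectly uniform image has no bimodality and is
    rejected under ``"auto"``.
    """
    data = np.asarray(img.image, dtype=float)
    if threshold == "auto":
        if data.min() == data.max():
            raise ValueError("uniform image: automatic threshold needs a bimodal histogram")
        thr = float(threshold_otsu(data))
        mask = data > thr
    else:
        thr = float(threshold)
        mask = data >= thr
    if invert:
        mask = ~mask
    return PlasmaMask(mask=mask, pixel_size=img.pixel_size)


def plasma_area(mask: PlasmaMask) -> float:
    """Wetted area S in mm^2: true-pixel count times pixel_size^2 (um^2),
    divided by 1e6."""
    return float(mask.mask.sum()) * mask.pixel_size**2 / 1.0e6


def volume_from_area(S: float, h: float) -> float:
    """Plasma volume V = S*h in uL, with S in mm^2 and h in um
    (1 mm^2 * um = 1e-3 uL)."""
    if S < 0:
        raise ValueError(f"area must be nonnegative, got {S}")
    if not h > 0:
        raise ValueError(f"channel height must be positive, got {h}")
    return S * h * 1.0e-3


def curve_from_images(
    images: list[ReservoirImage],
    h: float,
    threshold: float | str = "auto",
    invert: bool = False,
    area: float | None = None,
    label: str = "",
) -> FiltrationCurve:
    """Assemble a filtration curve from a time-ordered image series.

    Each frame is segmented, its wetted area converted to a volume via
    V = S*h, and the (timestamp, volume) pairs packed into a
    :class:`~plasmasep.estimation.FiltrationCurve`.  ``area`` is the
    device's effective filtration area if known (needed later for fitting).
    """
    if len(images) < 3:
        raise ValueError(f"need >= 3 images, got {len(images)}")
    if any(im.timestamp is None for im in images):
        raise ValueError("every image needs a timestamp")
    times = np.array([im.timestamp for im in images], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("image timestamps must be strictly increasing")
    volumes = np.array(
        [
            volume_from_area(plasma_area(segment_plasma(im, threshold, invert)), h)
            for im in images
        ]
    )
    return FiltrationCurve(times=times, volumes=volumes, area=area, label=label)
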