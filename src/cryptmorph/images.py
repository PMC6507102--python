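"""Grayscale image containers and TIFF I/O.

En-face SHG acquisitions are single-plane grayscale frames, nominally
512x512 px at 14-bit depth with a 522/512 um/px pitch.  ``GrayImage``
carries the raw integer counts plus acquisition metadata; ``NormImage``
is the [0, 1]-rescaled view used by segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: Default pixel pitch: a 522 um field of view mapped onto 512 pixels.
DEFAULT_PITCH_UM = 522.0 / 512.0
DEFAULT_BIT_DEPTH = 14


class BitDepthError(ValueError):
    """Pixel values exceed the declared bit depth."""


class ChannelError(ValueError):
    """Image is not a single-plane grayscale frame."""


@dataclass
class GrayImage:
    """A single grayscale acquisition.

    Parameters
    ----------
    pixels
        2D array of nonnegative integer counts.
    bit_depth
        Bits per pixel; intensities must lie in ``[0, 2**bit_depth - 1]``.
    pixel_pitch_um
        Physical size of one pixel in micrometres.
    metadata
        Hierarchy labels (cohort, mouse, location, depth_um, image id ...).
    """

    pixels: np.ndarray
    bit_depth: int = DEFAULT_BIT_DEPTH
    pixel_pitch_um: float = DEFAULT_PITCH_UM
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ChannelError(
                f"expected a 2D grayscale image, got shape {self.pixels.shape}"
            )
        if self.pixels.size == 0:
            raise ValueError("empty image")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise TypeError("GrayImage pixels must be integer counts")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        lo, hi = int(self.pixels.min()), int(self.pixels.max())
        if lo < 0 or hi > self.max_value:
            raise BitDepthError(
                f"pixel values [{lo}, {hi}] outside [0, {self.max_value}] "
                f"for bit depth {self.bit_depth}"
            )

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class NormImage:
    """Intensity-rescaled image with values in [0, 1].

    ``degenerate`` marks a constant source image, which rescales to all
    zeros rather than dividing by zero.
    """

    pixels: np.ndarray
    pixel_pitch_um: float = DEFAULT_PITCH_UM
    metadata: dict = field(default_factory=dict)
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ChannelError("NormImage must be 2D")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("NormImage values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def rescale_intensity(image: GrayImage) -> NormImage:
    """Affinely map intensities onto [0, 1].

    Applies ``(v - min) / (max - min)`` so the darkest pixel maps to 0 and
    the brightest to 1.  A constant image has no contrast to stretch; it is
    returned as all zeros with ``degenerate=True`` and a warning.
    """
    px = image.pixels.astype(float)
    lo, hi = px.min(), px.max()
    if hi == lo:
        warnings.warn(
            "constant image: intensity rescaling is degenerate, returning zeros",
            stacklevel=2,
        )
        return NormImage(
            np.zeros_like(px),
            pixel_pitch_um=image.pixel_pitch_um,
            metadata=dict(image.metadata),
            degenerate=True,
        )
    return NormImage(
        (px - lo) / (hi - lo),
        pixel_pitch_um=image.pixel_pitch_um,
        metadata=dict(image.metadata),
    )


def read_gray_image(
    path: str | Path,
    pitch_um: float = DEFAULT_PITCH_UM,
    bit_depth: int = DEFAULT_BIT_DEPTH,
    allow_overrange: bool = False,
    metadata: dict | None = None,
) -> GrayImage:
    """Read a single-plane grayscale TIFF.

    The 14-bit data ships in a 16-bit container; values above
    ``2**bit_depth - 1`` are rejected unless ``allow_overrange`` is set,
    in which case the declared bit depth is widened to 16.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ChannelError(
            f"{path.name}: expected single-plane grayscale, got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError(f"{path.name}: expected integer pixel data, got {arr.dtype}")
    if arr.max() > 2**bit_depth - 1:
        if not allow_overrange:
            raise BitDepthError(
                f"{path.name}: max value {int(arr.max())} exceeds "
                f"{bit_depth}-bit range; pass allow_overrange=True to accept"
            )
        bit_depth = 16
    return GrayImage(
        arr, bit_depth=bit_depth, pixel_pitch_um=pitch_um, metadata=metadata or {}
    )


def write_gray_image(path: str | Path, image: GrayImage) -> Path:
    """Write as 16-bit grayscale TIFF (container for 14-bit data)."""
    path = Path(path)
    tifffile.imwrite(path, image.pixels.astype(np.uint16))
    return path


def write_label_map(path: str | Path, labels: np.ndarray) -> Path:
    """Write an integer label map as 16-bit TIFF."""
    labels = np.asarray(labels)
    if labels.max() > 65535:
        raise ValueError("more than 65535 labels cannot be stored in 16-bit TIFF")
    path = Path(path)
    tifffile.imwrite(path, labels.astype(np.uint16))
    return path
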