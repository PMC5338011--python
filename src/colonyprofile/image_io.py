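"""Reading, writing and normalizing the image formats the pipeline touches.

Channel images are single-plane grayscale TIFFs (8- or 16-bit), one file per
fluorophore. Pixel size is required metadata supplied by the caller; TIFF
resolution tags are deliberately ignored because tile-scan exports often
carry wrong values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

VALID_LABELS = ("green", "red")


class DegenerateWindowWarning(UserWarning):
    """Raised when an intensity rescale window has zero width."""


@dataclass
class ChannelImage:
    """One genotype's grayscale fluorescence field with pixel-size metadata.

    Parameters
    ----------
    pixels : ndarray
        2D array of non-negative intensities. Stored as float64 internally;
        values must lie in ``[0, 2**bit_depth - 1]``.
    bit_depth : int
        8 or 16.
    pixel_size_um : float
        Physical size of one pixel in micrometers (> 0).
    channel_label : str
        ``"green"`` (eGFP-tagged genotype) or ``"red"`` (mCherry-tagged).
    """

    pixels: np.ndarray
    bit_depth: int
    pixel_size_um: float
    channel_label: str = "green"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.channel_label not in VALID_LABELS:
            raise ValueError(
                f"channel_label must be one of {VALID_LABELS}, got {self.channel_label!r}"
            )
        hi = 2**self.bit_depth - 1
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > hi):
            raise ValueError(f"intensities must lie in [0, {hi}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    def copy(self) -> "ChannelImage":
        return replace(self, pixels=self.pixels.copy())


@dataclass
class ColonyImagePair:
    """Two registered channel images plus inoculation-zone geometry.

    The two channels must share dimensions and pixel size; registration is
    assumed (sequential acquisition on a fixed stage).
    """

    green: ChannelImage
    red: ChannelImage
    center_px: tuple[float, float] = field(default=(0.0, 0.0))
    inoc_radius_um: float = 0.0

    def __post_init__(self) -> None:
        if self.green.shape != self.red.shape:
            raise ValueError(
                f"channel dimensions differ: {self.green.shape} vs {self.red.shape}"
            )
        if self.green.pixel_size_um != self.red.pixel_size_um:
            raise ValueError("channel pixel sizes differ")
        if self.inoc_radius_um < 0:
            raise ValueError("inoc_radius_um must be >= 0")
        r, c = self.center_px
        nr, nc = self.green.shape
        if not (0 <= r <= nr - 1 and 0 <= c <= nc - 1):
            raise ValueError(f"center {self.center_px} outside image bounds {self.green.shape}")

    @property
    def pixel_size_um(self) -> float:
        return self.green.pixel_size_um


def read_channel(path: str | Path, pixel_size_um: float, channel_label: str) -> ChannelImage:
    """Read a single-plane grayscale TIFF as a :class:`ChannelImage`.

    Multi-channel / RGB files and bit depths other than 8 or 16 are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(
            f"unsupported: not single-channel grayscale (shape {arr.shape} in {path})"
        )
    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(f"unsupported bit depth: dtype {arr.dtype} in {path}")
    return ChannelImage(
        pixels=arr, bit_depth=bit_depth, pixel_size_um=pixel_size_um, channel_label=channel_label
    )


def write_channel(img: ChannelImage, path: str | Path) -> None:
    """Write a channel image as a grayscale TIFF at its native bit depth."""
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    tifffile.imwrite(Path(path), np.round(img.pixels).astype(dtype))


def to_8bit(
    img: ChannelImage,
    mode: str = "percentile",
    p_low: float = 0.35,
    p_high: float = 99.65,
) -> ChannelImage:
    """Linearly rescale an intensity window onto [0, 255].

    ``mode="minmax"`` uses the full data range; ``mode="percentile"`` (the
    default, approximating an automatic brightness/contrast adjustment)
    clips at the given percentiles. A zero-width window yields an all-zero
    image and a :class:`DegenerateWindowWarning`.
    """
    if mode == "minmax":
        lo, hi = float(img.pixels.min()), float(img.pixels.max())
    elif mode == "percentile":
        lo, hi = (float(v) for v in np.percentile(img.pixels, [p_low, p_high]))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if hi == lo:
        warnings.warn(
            "degenerate intensity window (zero width); output is all zeros",
            DegenerateWindowWarning,
        )
        out = np.zeros_like(img.pixels)
    else:
        out = np.round(np.clip((img.pixels - lo) / (hi - lo), 0.0, 1.0) * 255.0)
    return ChannelImage(
        pixels=out,
        bit_depth=8,
        pixel_size_um=img.pixel_size_um,
        channel_label=img.channel_label,
    )


def overlay_pseudocolor(pair: ColonyImagePair, out_path: str | Path | None = None) -> np.ndarray:
    """Build a cyan/magenta pseudo-color overlay of the two channels.

    Green intensity g renders as cyan (0, g, g) and red intensity r as
    magenta (r, 0, r); the two are combined additively with clipping at 255,
    so (R, G, B) = (r, g, min(g + r, 255)). Regions where both signals are
    saturated appear white. Both channels must be 8-bit.
    """
    if pair.green.bit_depth != 8 or pair.red.bit_depth != 8:
        raise ValueError("overlay requires 8-bit channels; apply to_8bit first")
    g = pair.green.pixels
    r = pair.red.pixels
    rgb = np.stack([r, g, np.clip(g + r, 0, 255)], axis=-1).astype(np.uint8)
    if out_path is not None:
        iio.imwrite(Path(out_path), rgb)
    return rgb
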