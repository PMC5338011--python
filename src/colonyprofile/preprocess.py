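"""Image coarsening and circular intensity smoothing applied before radial analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from skimage.transform import resize

from colonyprofile.image_io import ChannelImage


@dataclass
class PreprocessParams:
    """Coarsening factor (default 8) and arc-length smoothing window (default ~10 um)."""

    coarsen_factor: int = 8
    smooth_window_um: float = 10.0

    def __post_init__(self) -> None:
        if self.coarsen_factor < 1:
            raise ValueError("coarsen_factor must be >= 1")
        if self.smooth_window_um < 0:
            raise ValueError("smooth_window_um must be >= 0")


def coarsen(img: ChannelImage, factor: int) -> ChannelImage:
    """Downsample by an integer factor using bicubic interpolation.

    Output dimensions are ``floor(input / factor)`` per axis and the pixel
    size is multiplied by ``factor``. An anti-aliasing prefilter is applied
    for factors > 1. Factor 1 returns an identical copy.

    A point at original pixel coordinate ``p`` maps to coarse coordinate
    ``(p + 0.5) / factor - 0.5`` (pixel-center convention).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return img.copy()
    nr, nc = img.shape
    if factor > nr or factor > nc:
        raise ValueError(f"factor {factor} exceeds image dimensions {img.shape}")
    out_shape = (nr // factor, nc // factor)
    out = resize(
        img.pixels,
        out_shape,
        order=3,
        anti_aliasing=True,
        preserve_range=True,
        mode="reflect",
    )
    out = np.clip(out, 0, img.max_value)
    return ChannelImage(
        pixels=out,
        bit_depth=img.bit_depth,
        pixel_size_um=img.pixel_size_um * factor,
        channel_label=img.channel_label,
    )


def coarse_coords(coord: float, factor: int) -> float:
    """Map an original-image pixel coordinate to the coarsened grid."""
    return (coord + 0.5) / factor - 0.5


def smooth_circular(values: np.ndarray, spacing_um: float, window_um: float) -> np.ndarray:
    """Circular (wrap-around) moving average over a closed intensity circle.

    The window spans ``round(window_um / spacing_um)`` samples, forced odd
    with a minimum of 1 (so windows narrower than one sample degrade to the
    identity). The uniform kernel preserves the circular mean exactly and
    never extends the value range.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    if spacing_um <= 0:
        raise ValueError("spacing_um must be > 0")
    if window_um < 0:
        raise ValueError("window_um must be >= 0")
    w = int(round(window_um / spacing_um))
    if w < 1:
        w = 1
    if w % 2 == 0:
        w += 1
    if w == 1:
        return values.copy()
    return uniform_filter1d(values, size=w, mode="wrap")
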