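"""Per-radius circular intensity profiles for both channels.

Circles are marched outward from the edge of the inoculation zone. Angles
are measured in image coordinates: theta = 0 along +x (columns), counter-
clockwise positive with +y pointing up (i.e. toward decreasing row index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from colonyprofile.image_io import ChannelImage, ColonyImagePair
from colonyprofile.preprocess import PreprocessParams, smooth_circular

logger = logging.getLogger(__name__)


@dataclass
class RadialProfile:
    """Smoothed circular intensity samples for both channels at one radius."""

    radius_um: float
    thetas: np.ndarray
    green_values: np.ndarray
    red_values: np.ndarray
    spacing_um: float

    def __post_init__(self) -> None:
        self.thetas = np.asarray(self.thetas, dtype=np.float64)
        self.green_values = np.asarray(self.green_values, dtype=np.float64)
        self.red_values = np.asarray(self.red_values, dtype=np.float64)
        n = len(self.thetas)
        if n < 8:
            raise ValueError("a profile needs at least 8 angular samples")
        if len(self.green_values) != n or len(self.red_values) != n:
            raise ValueError("thetas and channel values must have equal length")

    @property
    def n_points(self) -> int:
        return len(self.thetas)


@dataclass
class RadialSweepParams:
    """Radius grid and angular sampling density for the sweep.

    ``r_start_um=None`` defaults to the pair's inoculation radius;
    ``target_arc_spacing_um=None`` defaults to one (coarsened) pixel.
    """

    r_end_um: float
    r_start_um: float | None = None
    dr_um: float = 10.0
    target_arc_spacing_um: float | None = None

    def __post_init__(self) -> None:
        if self.r_start_um is not None and self.r_start_um < 0:
            raise ValueError("r_start_um must be >= 0")
        if self.r_start_um is not None and self.r_end_um <= self.r_start_um:
            raise ValueError("r_end_um must exceed r_start_um")
        if self.dr_um <= 0:
            raise ValueError("dr_um must be > 0")


def n_points_for_radius(radius_um: float, target_arc_spacing_um: float) -> int:
    """Number of angular samples so arc spacing ~= target.

    Rounded to a multiple of 4 (minimum 8) so that a 90-degree image
    rotation corresponds to an exact circular shift of the sample grid.
    """
    n = int(round(2.0 * np.pi * radius_um / target_arc_spacing_um / 4.0)) * 4
    return max(8, n)


def sample_circle(
    img: ChannelImage,
    center_px: tuple[float, float],
    radius_um: float,
    n_points: int,
) -> np.ndarray:
    """Bilinearly sample intensities on a circle of the given physical radius.

    Samples are taken at ``theta_k = 2 pi k / n_points``. Raises if any
    sample falls outside the image, naming the first offending angle.
    """
    if n_points < 8:
        raise ValueError("n_points must be >= 8")
    if radius_um < 0:
        raise ValueError("radius_um must be >= 0")
    r_px = radius_um / img.pixel_size_um
    cr, cc = center_px
    thetas = 2.0 * np.pi * np.arange(n_points) / n_points
    rows = cr - r_px * np.sin(thetas)
    cols = cc + r_px * np.cos(thetas)
    nr, nc = img.shape
    bad = (rows < 0) | (rows > nr - 1) | (cols < 0) | (cols > nc - 1)
    if bad.any():
        k = int(np.argmax(bad))
        raise ValueError(
            f"circle of radius {radius_um} um exits image bounds, first at "
            f"theta = {thetas[k]:.4f} rad"
        )
    return map_coordinates(img.pixels, np.array([rows, cols]), order=1, mode="nearest")


def circle_fits(img: ChannelImage, center_px: tuple[float, float], radius_um: float) -> bool:
    """True if the full circle lies within image bounds."""
    r_px = radius_um / img.pixel_size_um
    cr, cc = center_px
    nr, nc = img.shape
    return (
        cr - r_px >= 0 and cr + r_px <= nr - 1 and cc - r_px >= 0 and cc + r_px <= nc - 1
    )


def radial_sweep(
    pair: ColonyImagePair,
    params: RadialSweepParams,
    pp: PreprocessParams | None = None,
) -> list[RadialProfile]:
    """Extract smoothed circular profiles at each radius of the sweep.

    Both channels are sampled on an identical theta grid, then smoothed with
    a circular moving average of ``pp.smooth_window_um``. Radii whose circles
    exit the image are truncated from the sweep with a logged warning; if
    even the start radius does not fit, an error is raised.

    Coarsening is NOT applied here; pass an already-coarsened pair (see
    :func:`colonyprofile.patch_stats.patch_width_curve`).
    """
    if pp is None:
        pp = PreprocessParams(coarsen_factor=1)
    r_start = params.r_start_um if params.r_start_um is not None else pair.inoc_radius_um
    if params.r_end_um <= r_start:
        raise ValueError("r_end_um must exceed the start radius")
    target = (
        params.target_arc_spacing_um
        if params.target_arc_spacing_um is not None
        else pair.pixel_size_um
    )
    if not circle_fits(pair.green, pair.center_px, r_start):
        raise ValueError(f"start radius {r_start} um already exits image bounds")

    radii = np.arange(r_start, params.r_end_um + params.dr_um / 2.0, params.dr_um)
    profiles: list[RadialProfile] = []
    for r in radii:
        if not circle_fits(pair.green, pair.center_px, r):
            logger.warning(
                "sweep truncated at radius %.1f um: circle exits image bounds", r
            )
            break
        n = n_points_for_radius(r, target)
        spacing = 2.0 * np.pi * r / n
        thetas = 2.0 * np.pi * np.arange(n) / n
        g = sample_circle(pair.green, pair.center_px, r, n)
        rd = sample_circle(pair.red, pair.center_px, r, n)
        g = smooth_circular(g, spacing, pp.smooth_window_um)
        rd = smooth_circular(rd, spacing, pp.smooth_window_um)
        profiles.append(
            RadialProfile(
                radius_um=float(r),
                thetas=thetas,
                green_values=g,
                red_values=rd,
                spacing_um=spacing,
            )
        )
    return profiles
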