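"""Synthetic two-channel colony images with exactly known radial strand structure.

The generator paints an inoculation disc of well-mixed speckle surrounded by
an annulus of alternating angular sectors of two genotypes. All modes share
one representation: a table of sector layouts, one row per radius at
``truth_dr_um`` resolution. The renderer and the :class:`GroundTruth` oracle
read the same table, so pipeline output can be compared against analytic
strand widths without registration error.

Modes
-----
``fixed_sectors``
    Constant angular sectors; physical widths grow linearly with radius.
``narrowing`` / ``widening``
    Equal alternating sectors whose even count per radius tracks a linear
    target mean width, so physical strand width decreases (narrowing) or
    increases (widening) with radius. Deterministic.
``boundary_walk``
    Boundaries take Gaussian angular steps; adjacent boundaries that cross
    annihilate (neutral demixing) and new zero-width wedges may be inserted
    at a configurable branching rate (mixing pressure).

This is a test harness with exactly known truth, not a growth model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from colonyprofile.image_io import ChannelImage, ColonyImagePair

GENOTYPES = (0, 1)  # 0 -> green channel signal, 1 -> red channel signal


@dataclass
class SyntheticColonySpec:
    """Parameters of the synthetic colony image generator.

    ``width_start_um`` / ``width_end_um`` define the linear target mean
    strand width between the inoculation edge and the colony edge for the
    ``narrowing`` and ``widening`` modes; realized widths are recorded in
    the generated :class:`GroundTruth`, which is the comparison oracle.
    """

    image_size_px: int = 512
    pixel_size_um: float = 5.0
    inoc_radius_um: float = 1000.0  # ~2 mm diameter inoculation zone
    colony_radius_um: float = 2400.0
    mode: str = "fixed_sectors"  # fixed_sectors | narrowing | widening | boundary_walk
    n_strands_initial: int = 8
    width_start_um: float = 100.0
    width_end_um: float = 10.0
    walk_sigma: float = 0.0  # rad*sqrt(um); per-step angular sd = walk_sigma/sqrt(R)
    branching_rate: float = 0.0  # boundary-pair insertions per um front per um radius
    truth_dr_um: float = 10.0  # radial resolution of the sector table
    signal_level: float = 200.0
    background_level: float = 20.0
    noise_sd: float = 10.0
    blur_sigma_um: float = 0.0
    speckle_grain_um: float = 10.0
    pioneer_ring_um: float = 0.0  # width of a single-genotype band at the periphery
    pioneer_genotype: int = 1
    coffee_ring: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.colony_radius_um <= self.inoc_radius_um:
            raise ValueError("colony_radius_um must exceed inoc_radius_um")
        if self.n_strands_initial < 2 or self.n_strands_initial % 2:
            raise ValueError("n_strands_initial must be even and >= 2")
        if not self.signal_level > self.background_level >= 0:
            raise ValueError("require signal_level > background_level >= 0")
        if self.mode not in ("fixed_sectors", "narrowing", "widening", "boundary_walk"):
            raise ValueError(f"unknown mode {self.mode!r}")
        half = self.image_size_px / 2 * self.pixel_size_um
        if self.colony_radius_um > half:
            raise ValueError(
                f"colony radius {self.colony_radius_um} um does not fit in a "
                f"{self.image_size_px} px image at {self.pixel_size_um} um/px"
            )


@dataclass
class GroundTruth:
    """Exact sector layout per radius: the oracle for parameter recovery.

    ``sectors[i]`` lists ``(theta_start, theta_end, genotype)`` tuples
    partitioning [0, 2 pi) at ``radii_um[i]``; a single-genotype front is a
    single sector spanning the full circle.
    """

    radii_um: np.ndarray
    sectors: list[list[tuple[float, float, int]]] = field(default_factory=list)

    def n_boundaries(self, i: int) -> int:
        """Number of genotype boundaries at radius index ``i``."""
        secs = self.sectors[i]
        if len(secs) <= 1:
            return 0
        return sum(
            1
            for j in range(len(secs))
            if secs[j][2] != secs[(j + 1) % len(secs)][2]
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r, secs in zip(self.radii_um, self.sectors):
            for t0, t1, g in secs:
                rows.append(
                    {"radius_um": r, "theta_start": t0, "theta_end": t1, "genotype": g}
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(Path(path), index=False)


def _sector_extent(t0: float, t1: float) -> float:
    ext = (t1 - t0) % (2 * np.pi)
    return 2 * np.pi if ext == 0.0 else ext


def truth_patch_width(gt: GroundTruth, radius_um: float) -> dict[int, float]:
    """Analytic mean strand width per genotype at the nearest truth radius.

    Width of a sector is its angular extent times the radius (arc length).
    A genotype with no sectors maps to NaN, mirroring the no-crossing case.
    """
    radii = np.asarray(gt.radii_um)
    if radius_um < radii.min() - 1e-9 or radius_um > radii.max() + 1e-9:
        raise ValueError(f"radius {radius_um} outside ground-truth range")
    i = int(np.argmin(np.abs(radii - radius_um)))
    secs = gt.sectors[i]
    out: dict[int, float] = {}
    for g in GENOTYPES:
        widths = [_sector_extent(t0, t1) * radius_um for t0, t1, gg in secs if gg == g]
        out[g] = float(np.mean(widths)) if widths else float("nan")
    return out


# ---------------------------------------------------------------------------
# sector-table construction
#
# Working representation: "lifted" strictly increasing boundary angles
# starts[0] < starts[1] < ... < starts[m-1] < starts[0] + 2*pi, where sector i
# spans starts[i] -> starts[i+1] (circularly) with genotype genos[i].
# Genotypes always alternate, so annihilating sector i merges its equal-
# genotype neighbors and removes exactly two boundaries.
# ---------------------------------------------------------------------------


def _snapshot(starts: list[float], genos: list[int]) -> list[tuple[float, float, int]]:
    if not starts:
        return [(0.0, 2 * np.pi, genos[0])]
    m = len(starts)
    return [
        (starts[i] % (2 * np.pi), starts[(i + 1) % m] % (2 * np.pi), genos[i])
        for i in range(m)
    ]


def _annihilate(starts: list[float], genos: list[int], i: int) -> tuple[list[float], list[int]]:
    """Remove collapsed sector i (boundaries i and i+1)."""
    m = len(starts)
    if m == 2:
        survivor = genos[1 - i]
        return [], [survivor]
    j = (i + 1) % m
    keep = [k for k in range(m) if k not in (i, j)]
    return [starts[k] for k in keep], [genos[k] for k in keep]


def _relift(starts: list[float]) -> list[float]:
    """Restore the strictly-increasing lifted representation."""
    if not starts:
        return starts
    out = [starts[0] % (2 * np.pi)]
    for s in starts[1:]:
        s = s % (2 * np.pi)
        while s < out[-1]:
            s += 2 * np.pi
        out.append(s)
    return out


def _collapse_all(starts: list[float], genos: list[int]) -> tuple[list[float], list[int]]:
    """Annihilate every sector whose width has become non-positive."""
    changed = True
    while changed and starts:
        changed = False
        m = len(starts)
        for i in range(m):
            nxt = starts[(i + 1) % m] + (2 * np.pi if i == m - 1 else 0.0)
            if nxt <= starts[i]:
                starts, genos = _annihilate(starts, genos, i)
                starts = _relift(starts)
                changed = True
                break
    return starts, genos


def _insert_wedge(
    starts: list[float], genos: list[int], t: float, half_width: float
) -> tuple[list[float], list[int]]:
    """Insert an opposite-genotype wedge of 2*half_width centered at angle t."""
    m = len(starts)
    if m == 0:
        host = genos[0]
        return _relift([t - half_width, t + half_width]), [1 - host, host]
    # host sector index in lifted coordinates
    t_l = starts[0] + (t - starts[0]) % (2 * np.pi)
    i = int(np.searchsorted(starts, t_l, side="right")) - 1
    hi = starts[i + 1] if i + 1 < m else starts[0] + 2 * np.pi
    if t_l - half_width <= starts[i] or t_l + half_width >= hi:
        return starts, genos  # wedge would overlap a boundary; skip
    host = genos[i]
    starts = starts[: i + 1] + [t_l - half_width, t_l + half_width] + starts[i + 1 :]
    genos = genos[: i + 1] + [1 - host, host] + genos[i + 1 :]
    return starts, genos


def _truth_radii(spec: SyntheticColonySpec) -> np.ndarray:
    return np.arange(
        spec.inoc_radius_um,
        spec.colony_radius_um + spec.truth_dr_um / 2,
        spec.truth_dr_um,
    )


def _target_width(spec: SyntheticColonySpec, r: float) -> float:
    frac = (r - spec.inoc_radius_um) / (spec.colony_radius_um - spec.inoc_radius_um)
    frac = min(max(frac, 0.0), 1.0)
    return spec.width_start_um + (spec.width_end_um - spec.width_start_um) * frac


def _build_sector_table(
    spec: SyntheticColonySpec, rng: np.random.Generator | None
) -> GroundTruth:
    radii = _truth_radii(spec)
    if spec.mode == "fixed_sectors":
        m = spec.n_strands_initial
        starts = list(2 * np.pi * np.arange(m) / m)
        genos = [i % 2 for i in range(m)]
        snap = _snapshot(starts, genos)
        return GroundTruth(radii_um=radii, sectors=[list(snap) for _ in radii])

    if spec.mode in ("narrowing", "widening"):
        # equal alternating sectors per radius row; the even sector count
        # tracks the linear target width. Rendering quantizes pixels to the
        # nearest row, so each profiled circle sees exactly one row's layout.
        sectors = []
        for r in radii:
            m = max(2, 2 * round(np.pi * r / _target_width(spec, r)))
            starts = list(2 * np.pi * np.arange(m) / m)
            genos = [i % 2 for i in range(m)]
            sectors.append(_snapshot(starts, genos))
        return GroundTruth(radii_um=radii, sectors=sectors)

    # boundary_walk
    assert rng is not None
    m = spec.n_strands_initial
    starts = list(2 * np.pi * np.arange(m) / m)
    genos = [i % 2 for i in range(m)]
    sectors = [_snapshot(starts, genos)]
    for r in radii[1:]:
        if starts and spec.walk_sigma > 0:
            sd = spec.walk_sigma / np.sqrt(r)
            steps = rng.normal(0.0, sd, size=len(starts))
            starts = [s + d for s, d in zip(starts, steps)]
            starts, genos = _collapse_all(starts, genos)
        if spec.branching_rate > 0:
            p = min(spec.branching_rate * 2 * np.pi * r * spec.truth_dr_um, 1.0)
            if rng.random() < p:
                t = rng.uniform(0, 2 * np.pi)
                starts, genos = _insert_wedge(starts, genos, t, 1.0 / r)  # ~1 um half-arc
        sectors.append(_snapshot(starts, genos))
    return GroundTruth(radii_um=radii, sectors=sectors)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _render(spec: SyntheticColonySpec, gt: GroundTruth) -> ColonyImagePair:
    """Rasterize the sector table into a two-channel 8-bit image pair.

    Annulus pixels use the sector row of their nearest truth radius, so a
    circle sampled exactly at a truth radius never straddles two rows.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size_px
    c = (n - 1) / 2.0
    rows, cols = np.mgrid[0:n, 0:n].astype(np.float64)
    x = (cols - c) * spec.pixel_size_um
    y = (c - rows) * spec.pixel_size_um  # +y up: theta is CCW in image coords
    r = np.hypot(x, y)
    theta = np.mod(np.arctan2(y, x), 2 * np.pi)

    genotype = np.full((n, n), -1, dtype=np.int64)  # -1 = outside colony

    # inoculation disc: well-mixed speckle on a grain grid
    inoc = r < spec.inoc_radius_um
    grain = max(spec.speckle_grain_um, spec.pixel_size_um)
    gi = np.floor(x / grain).astype(np.int64)
    gj = np.floor(y / grain).astype(np.int64)
    gi -= gi.min()
    gj -= gj.min()
    grid = rng.integers(0, 2, size=(gi.max() + 1, gj.max() + 1))
    genotype[inoc] = grid[gi[inoc], gj[inoc]]

    # annulus: assign per pixel from the nearest truth-radius sector row
    annulus = (r >= spec.inoc_radius_um) & (r <= spec.colony_radius_um)
    idx = np.round((r - spec.inoc_radius_um) / spec.truth_dr_um).astype(np.int64)
    idx = np.clip(idx, 0, len(gt.radii_um) - 1)
    sorted_rows = []
    for secs in gt.sectors:
        starts = np.array([s[0] for s in secs])
        order = np.argsort(starts)
        sorted_rows.append((starts[order], np.array([secs[i][2] for i in order])))
    for i in np.unique(idx[annulus]):
        mask = annulus & (idx == i)
        starts, gs = sorted_rows[i]
        if len(starts) == 1:
            genotype[mask] = gs[0]
        else:
            k = np.searchsorted(starts, theta[mask], side="right") - 1
            genotype[mask] = gs[k]  # k == -1 wraps to the last sector

    if spec.pioneer_ring_um > 0:
        band = annulus & (r >= spec.colony_radius_um - spec.pioneer_ring_um)
        genotype[band] = spec.pioneer_genotype

    channels = []
    for g in GENOTYPES:
        img = np.where(genotype == g, spec.signal_level, spec.background_level).astype(
            np.float64
        )
        if spec.coffee_ring:
            rim = (r >= spec.inoc_radius_um * 0.9) & inoc & (genotype == g)
            img[rim] = min(spec.signal_level * 1.25, 255.0)
        if spec.blur_sigma_um > 0:
            img = gaussian_filter(img, sigma=spec.blur_sigma_um / spec.pixel_size_um)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        channels.append(np.clip(np.round(img), 0, 255))

    green = ChannelImage(channels[0], 8, spec.pixel_size_um, "green")
    red = ChannelImage(channels[1], 8, spec.pixel_size_um, "red")
    return ColonyImagePair(
        green=green, red=red, center_px=(c, c), inoc_radius_um=spec.inoc_radius_um
    )


def generate_sector_colony(spec: SyntheticColonySpec) -> tuple[ColonyImagePair, GroundTruth]:
    """Colony with deterministically placed alternating sectors.

    Handles modes ``fixed_sectors``, ``narrowing`` and ``widening``.
    Deterministic given ``spec.seed`` (the seed only feeds speckle and noise).
    """
    if spec.mode not in ("fixed_sectors", "narrowing", "widening"):
        raise ValueError(f"generate_sector_colony does not handle mode {spec.mode!r}")
    gt = _build_sector_table(spec, None)
    return _render(spec, gt), gt


def generate_boundary_walk_colony(
    spec: SyntheticColonySpec,
) -> tuple[ColonyImagePair, GroundTruth]:
    """Colony whose sector boundaries follow annihilating random walks."""
    if spec.mode != "boundary_walk":
        raise ValueError("spec.mode must be 'boundary_walk'")
    rng = np.random.default_rng(spec.seed + 1)  # independent of the noise stream
    gt = _build_sector_table(spec, rng)
    return _render(spec, gt), gt


def generate_colony(spec: SyntheticColonySpec) -> tuple[ColonyImagePair, GroundTruth]:
    """Dispatch on ``spec.mode``."""
    if spec.mode == "boundary_walk":
        return generate_boundary_walk_colony(spec)
    return generate_sector_colony(spec)
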