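"""Core patch-width statistic: per-radius Otsu threshold, corrected signal,
circular crossing statistics, and the mean clonal patch width curve.

A "patch" (clonal strand) is a maximal contiguous arc of the sampling circle
where the threshold-corrected fluorescence of one channel is strictly above
zero. Crossings are sign changes of the corrected signal between consecutive
circular samples; their density determines the mean patch width. Radii with
no crossings (a channel covering the whole circle, or absent) are flagged
``reliable=False`` and excluded from curve summaries by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from colonyprofile.image_io import ColonyImagePair
from colonyprofile.preprocess import PreprocessParams, coarse_coords, coarsen
from colonyprofile.radial_profile import RadialProfile, RadialSweepParams, radial_sweep

CHANNELS = ("green", "red")


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold of a 1D intensity sample.

    Intensities are histogrammed into ``n_bins`` bins over ``[min, max]``;
    the returned threshold is the bin edge that maximizes the between-class
    variance ``w0 * w1 * (mu0 - mu1)**2`` (class means taken at bin
    centers). Candidate cuts are restricted to edges where the partition
    actually changes (the bin below the edge is non-empty), which realizes
    the smallest-threshold tie-break across runs of empty bins. A constant
    input returns the constant value (degenerate case; see
    :func:`is_degenerate`).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("values must be non-empty")
    lo, hi = float(values.min()), float(values.max())
    if is_degenerate(values) or lo + (hi - lo) / n_bins == lo:
        return lo
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum()
    # cut after bin k: class0 = bins[0..k], class1 = bins[k+1..]
    w0 = np.cumsum(counts)[:-1].astype(np.float64)
    w1 = total - w0
    csum = np.cumsum(counts * centers)[:-1]
    valid = (counts[:-1] > 0) & (w1 > 0)
    sigma_b = np.zeros(n_bins - 1)
    mu0 = np.divide(csum, w0, out=np.zeros_like(sigma_b), where=valid)
    mu1 = np.divide(csum[-1] + counts[-1] * centers[-1] - csum, w1,
                    out=np.zeros_like(sigma_b), where=valid)
    sigma_b[valid] = w0[valid] * w1[valid] * (mu0[valid] - mu1[valid]) ** 2
    k = int(np.argmax(sigma_b))
    return float(edges[k + 1])


def is_degenerate(values: np.ndarray) -> bool:
    """True if the sample is constant, making any threshold meaningless.

    A relative tolerance absorbs floating-point dust left by the circular
    smoothing filter on constant circles.
    """
    values = np.asarray(values, dtype=np.float64)
    lo, hi = float(values.min()), float(values.max())
    return hi - lo <= 1e-9 * max(1.0, abs(lo), abs(hi))


def corrected_signal(values: np.ndarray, threshold: float) -> np.ndarray:
    """Elementwise ``values - threshold`` (signed corrected fluorescence)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return np.asarray(values, dtype=np.float64) - threshold


def circular_runs(signal: np.ndarray, spacing_um: float) -> tuple[int, list[float]]:
    """Crossing count and above-zero run lengths on a closed circle.

    The signal is binarized as ``signal > 0`` (exact zeros fall in the
    below class). Runs are maximal on the circular topology, so a run may
    wrap through index 0; run length is (samples in run) * ``spacing_um``.
    Crossings are the sign changes between consecutive circular samples
    (always even). An all-above circle is one run of the full circumference
    with zero crossings; an all-below circle has no runs.
    """
    signal = np.asarray(signal, dtype=np.float64)
    n = signal.size
    if n == 0:
        raise ValueError("signal must be non-empty")
    if spacing_um <= 0:
        raise ValueError("spacing_um must be > 0")
    above = signal > 0
    n_crossings = int(np.count_nonzero(above != np.roll(above, 1)))
    if above.all():
        return 0, [n * spacing_um]
    if not above.any():
        return 0, []
    # run starts: above here, below at previous (circular) index
    starts = np.flatnonzero(above & ~np.roll(above, 1))
    ends = np.flatnonzero(~above & np.roll(above, 1))  # first below after a run
    # pair each start with the next end, circularly
    runs: list[float] = []
    ends_sorted = np.sort(ends)
    for s in starts:
        nxt = ends_sorted[np.searchsorted(ends_sorted, s, side="right") % len(ends_sorted)]
        length = (nxt - s) % n
        runs.append(length * spacing_um)
    return n_crossings, runs


@dataclass
class ChannelPatchStats:
    """Patch statistics of one channel at one radius."""

    threshold: float
    degenerate_threshold: bool
    n_crossings: int
    n_patches: int
    mean_patch_width_um: float  # NaN when undefined (no above-zero run)
    covered_fraction: float
    reliable: bool


@dataclass
class PatchStatsAtRadius:
    radius_um: float
    spacing_um: float
    green: ChannelPatchStats
    red: ChannelPatchStats

    @property
    def combined_mean_width_um(self) -> float:
        """Mean of the two channels' widths weighted by their patch counts.

        Only reliable channels with a defined width contribute; NaN if none.
        """
        num = 0.0
        den = 0
        for ch in (self.green, self.red):
            if ch.reliable and np.isfinite(ch.mean_patch_width_um) and ch.n_patches > 0:
                num += ch.mean_patch_width_um * ch.n_patches
                den += ch.n_patches
        return num / den if den else float("nan")

    @property
    def reliable(self) -> bool:
        return self.green.reliable and self.red.reliable


def _channel_stats(
    values: np.ndarray, spacing_um: float, fallback: np.ndarray | None = None
) -> ChannelPatchStats:
    """Stats for one channel's circle; ``fallback`` supplies the pooled
    two-channel sample used to place a constant circle above or below
    threshold (a channel with no internal contrast carries no such
    information on its own)."""
    degenerate = is_degenerate(values)
    if degenerate and fallback is not None and not is_degenerate(fallback):
        threshold = otsu_threshold(fallback)
    else:
        threshold = otsu_threshold(values)
    n_crossings, runs = circular_runs(corrected_signal(values, threshold), spacing_um)
    circumference = len(values) * spacing_um
    covered = sum(runs) / circumference
    n_patches = len(runs)
    mean_width = float(np.mean(runs)) if runs else float("nan")
    reliable = n_crossings > 0 and not degenerate
    return ChannelPatchStats(
        threshold=threshold,
        degenerate_threshold=degenerate,
        n_crossings=n_crossings,
        n_patches=n_patches,
        mean_patch_width_um=mean_width,
        covered_fraction=covered,
        reliable=reliable,
    )


def patch_stats_at_radius(profile: RadialProfile) -> PatchStatsAtRadius:
    """Per-radius statistics for both channels, analyzed independently.

    A constant (degenerate) channel is classified against the pooled Otsu
    threshold of both channels so that a uniformly dominant genotype reports
    full coverage and an absent one reports none; such radii are flagged
    unreliable either way.
    """
    pooled = np.concatenate([profile.green_values, profile.red_values])
    return PatchStatsAtRadius(
        radius_um=profile.radius_um,
        spacing_um=profile.spacing_um,
        green=_channel_stats(profile.green_values, profile.spacing_um, fallback=pooled),
        red=_channel_stats(profile.red_values, profile.spacing_um, fallback=pooled),
    )


@dataclass
class PatchWidthCurve:
    """Ordered per-radius patch statistics over the radial sweep."""

    stats: list[PatchStatsAtRadius]
    sweep_params: RadialSweepParams | None = None
    preprocess_params: PreprocessParams | None = None

    def __post_init__(self) -> None:
        radii = [s.radius_um for s in self.stats]
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("radii must be strictly increasing")

    @property
    def radii_um(self) -> np.ndarray:
        return np.array([s.radius_um for s in self.stats])

    def combined_widths_um(self, reliable_only: bool = True) -> np.ndarray:
        out = []
        for s in self.stats:
            if reliable_only and not s.reliable:
                out.append(float("nan"))
            else:
                out.append(s.combined_mean_width_um)
        return np.array(out)

    def to_dataframe(self) -> pd.DataFrame:
        """One row per (radius, channel)."""
        rows = []
        for s in self.stats:
            for name in CHANNELS:
                ch: ChannelPatchStats = getattr(s, name)
                rows.append(
                    {
                        "radius_um": s.radius_um,
                        "channel": name,
                        "threshold": ch.threshold,
                        "n_crossings": ch.n_crossings,
                        "n_patches": ch.n_patches,
                        "mean_patch_width_um": ch.mean_patch_width_um,
                        "covered_fraction": ch.covered_fraction,
                        "reliable": ch.reliable,
                    }
                )
        return pd.DataFrame(rows)


def _coarsened_pair(pair: ColonyImagePair, pp: PreprocessParams) -> ColonyImagePair:
    if pp.coarsen_factor == 1:
        return pair
    f = pp.coarsen_factor
    return ColonyImagePair(
        green=coarsen(pair.green, f),
        red=coarsen(pair.red, f),
        center_px=(coarse_coords(pair.center_px[0], f), coarse_coords(pair.center_px[1], f)),
        inoc_radius_um=pair.inoc_radius_um,
    )


def patch_width_curve(
    pair: ColonyImagePair,
    sweep: RadialSweepParams,
    pp: PreprocessParams | None = None,
) -> PatchWidthCurve:
    """Full pipeline: coarsen, sweep circles, per-radius patch statistics."""
    if pp is None:
        pp = PreprocessParams()
    coarse = _coarsened_pair(pair, pp)
    profiles = radial_sweep(coarse, sweep, pp)
    stats = [patch_stats_at_radius(p) for p in profiles]
    return PatchWidthCurve(stats=stats, sweep_params=sweep, preprocess_params=pp)


def abundance_profile(
    pair: ColonyImagePair,
    sweep: RadialSweepParams,
    pp: PreprocessParams | None = None,
) -> pd.DataFrame:
    """Per-radius covered fraction of each channel from the thresholded circles."""
    curve = patch_width_curve(pair, sweep, pp)
    rows = []
    for s in curve.stats:
        rows.append(
            {
                "radius_um": s.radius_um,
                "green_fraction": s.green.covered_fraction,
                "red_fraction": s.red.covered_fraction,
                "green_reliable": s.green.reliable,
                "red_reliable": s.red.reliable,
            }
        )
    return pd.DataFrame(rows)
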