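import numpy as np
import pytest

from colonyprofile.image_io import ChannelImage, ColonyImagePair
from colonyprofile.preprocess import PreprocessParams
from colonyprofile.radial_profile import RadialSweepParams
from colonyprofile.synthetic_data import SyntheticColonySpec, generate_sector_colony


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def constant_image():
    return ChannelImage(np.full((64, 64), 100.0), 16, 1.0, "green")


def make_pair(green_px, red_px, pixel_size_um=1.0, center=None, inoc_radius_um=0.0):
    g = ChannelImage(green_px, 8, pixel_size_um, "green")
    r = ChannelImage(red_px, 8, pixel_size_um, "red")
    if center is None:
        center = ((green_px.shape[0] - 1) / 2, (green_px.shape[1] - 1) / 2)
    return ColonyImagePair(green=g, red=r, center_px=center, inoc_radius_um=inoc_radius_um)


@pytest.fixture(scope="session")
def small_sector_colony():
    """Noiseless 8-sector colony used by several recovery tests."""
    spec = SyntheticColonySpec(
        image_size_px=360,
        pixel_size_um=2.0,
        inoc_radius_um=100.0,
        colony_radius_um=320.0,
        mode="fixed_sectors",
        n_strands_initial=8,
        noise_sd=0.0,
        seed=11,
    )
    return generate_sector_colony(spec)


@pytest.fixture(scope="session")
def small_sweep():
    return RadialSweepParams(r_start_um=110.0, r_end_um=300.0, dr_um=10.0)


@pytest.fixture(scope="session")
def no_coarsen_pp():
    return PreprocessParams(coarsen_factor=1, smooth_window_um=4.0)


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept here so every test module shares the
# same reference implementations; they never call package internals)
# ---------------------------------------------------------------------------


def brute_force_otsu(values, n_bins=256):
    """Exhaustive search over all histogram cuts maximizing between-class variance."""
    values = np.asarray(values, dtype=float).ravel()
    lo, hi = values.min(), values.max()
    if lo == hi:
        return float(lo)
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_sigma, best_edge = -1.0, None
    for k in range(1, n_bins):  # class0 = bins [0, k), class1 = bins [k, n_bins)
        if counts[k - 1] == 0:
            continue  # partition unchanged since the previous candidate cut
        w0 = counts[:k].sum()
        w1 = counts[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        sigma = w0 * w1 * (mu0 - mu1) ** 2
        if sigma > best_sigma:
            best_sigma, best_edge = sigma, edges[k]
    return float(best_edge)


def brute_force_circular_runs(bits):
    """Enumerate maximal above-runs of a binary circular sequence by rotation."""
    bits = [bool(b) for b in bits]
    n = len(bits)
    crossings = sum(bits[i] != bits[(i + 1) % n] for i in range(n))
    if all(bits):
        return 0, [n]
    if not any(bits):
        return 0, []
    k = next(i for i in range(n) if not bits[i])
    rotated = [bits[(k + i) % n] for i in range(n)]
    runs, cur = [], 0
    for b in rotated:
        if b:
            cur += 1
        elif cur:
            runs.append(cur)
            cur = 0
    if cur:
        runs.append(cur)
    return crossings, runs
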