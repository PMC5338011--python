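import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colonyprofile.image_io import ChannelImage, ColonyImagePair
from colonyprofile.patch_stats import (
    PatchWidthCurve,
    abundance_profile,
    circular_runs,
    corrected_signal,
    is_degenerate,
    otsu_threshold,
    patch_stats_at_radius,
    patch_width_curve,
)
from colonyprofile.preprocess import PreprocessParams
from colonyprofile.radial_profile import RadialProfile, RadialSweepParams
from colonyprofile.synthetic_data import SyntheticColonySpec, generate_colony, truth_patch_width

from conftest import brute_force_circular_runs, brute_force_otsu, make_pair


class TestOtsu:
    def test_perfectly_bimodal(self):
        values = np.array([0.0] * 10 + [255.0] * 10)
        t = otsu_threshold(values)
        assert 0 < t < 255
        below = values <= t
        assert below.sum() == 10

    def test_against_brute_force_example(self):
        values = np.array([1.0, 1, 2, 2, 8, 9, 9])
        assert otsu_threshold(values) == brute_force_otsu(values)

    def test_constant_degenerate(self):
        values = np.array([5.0, 5.0, 5.0])
        assert otsu_threshold(values) == 5.0
        assert is_degenerate(values)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.array([]))

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force(self, data):
        kind = data.draw(st.sampled_from(["uniform", "normal", "bimodal"]))
        n = data.draw(st.integers(10, 400))
        seed = data.draw(st.integers(0, 2**31))
        rng = np.random.default_rng(seed)
        if kind == "uniform":
            values = rng.uniform(0, 255, n)
        elif kind == "normal":
            values = rng.normal(100, 25, n)
        else:
            values = np.concatenate(
                [rng.normal(30, 8, n // 2), rng.normal(180, 15, n - n // 2)]
            )
        assert otsu_threshold(values) == brute_force_otsu(values)


class TestCorrectedSignal:
    def test_subtraction(self):
        np.testing.assert_array_equal(
            corrected_signal(np.array([10.0, 20.0]), 15.0), [-5.0, 5.0]
        )

    def test_threshold_at_min_max(self, rng):
        v = rng.uniform(0, 100, 50)
        assert (corrected_signal(v, v.min()) >= 0).all()
        assert (corrected_signal(v, v.max()) <= 0).all()

    def test_nonfinite_threshold(self):
        with pytest.raises(ValueError):
            corrected_signal(np.array([1.0]), np.nan)


class TestCircularRuns:
    def test_worked_example(self):
        signal = np.array([1.0, 1, -1, 1, -1, -1])
        n_crossings, runs = circular_runs(signal, 10.0)
        assert n_crossings == 4
        assert sorted(runs) == [10.0, 20.0]

    def test_alternating(self):
        signal = np.array([1.0, -1] * 4)
        n_crossings, runs = circular_runs(signal, 3.0)
        assert n_crossings == 8
        assert runs == [3.0] * 4

    def test_all_above_wraps_full_circle(self):
        n_crossings, runs = circular_runs(np.ones(12), 2.0)
        assert n_crossings == 0
        assert runs == [24.0]

    def test_all_below(self):
        n_crossings, runs = circular_runs(-np.ones(12), 2.0)
        assert n_crossings == 0
        assert runs == []

    def test_zero_is_below(self):
        n_crossings, runs = circular_runs(np.array([0.0, 1.0, 0.0, 0.0]), 1.0)
        assert runs == [1.0]
        assert n_crossings == 2

    def test_wrap_through_zero_index(self):
        signal = np.array([1.0, -1, -1, 1])  # run spans indices 3,0
        _, runs = circular_runs(signal, 1.0)
        assert runs == [2.0]

    @pytest.mark.parametrize("n", range(1, 10))
    def test_exhaustive_small(self, n):
        for bits in itertools.product([0, 1], repeat=n):
            signal = np.where(np.array(bits) == 1, 1.0, -1.0)
            n_crossings, runs = circular_runs(signal, 1.0)
            exp_crossings, exp_runs = brute_force_circular_runs(bits)
            assert n_crossings == exp_crossings
            assert sorted(runs) == sorted(float(r) for r in exp_runs)

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=64), st.integers(0, 63))
    @settings(max_examples=100, deadline=None)
    def test_conservation_and_rotation(self, values, shift):
        signal = np.asarray(values)
        n_crossings, runs = circular_runs(signal, 1.0)
        _, below = circular_runs(-signal, 1.0)
        zeros = np.count_nonzero(signal == 0.0)
        assert sum(runs) + sum(below) + zeros == pytest.approx(len(signal))
        assert n_crossings % 2 == 0
        rc, rruns = circular_runs(np.roll(signal, shift), 1.0)
        assert rc == n_crossings
        assert sorted(rruns) == pytest.approx(sorted(runs))


def _profile(green, red, radius_um=100.0):
    n = len(green)
    thetas = 2 * np.pi * np.arange(n) / n
    return RadialProfile(radius_um, thetas, np.asarray(green, float),
                         np.asarray(red, float), 2 * np.pi * radius_um / n)


class TestPatchStatsAtRadius:
    def test_eight_sector_profile(self):
        # synthetic alternating profile: 8 sectors of 32 samples each
        n, radius = 256, 200.0
        sector = np.floor(np.arange(n) * 8 / n).astype(int)
        green = np.where(sector % 2 == 0, 200.0, 20.0)
        red = np.where(sector % 2 == 1, 200.0, 20.0)
        s = patch_stats_at_radius(_profile(green, red, radius))
        expected = 2 * np.pi * radius / 8
        for ch in (s.green, s.red):
            assert ch.n_patches == 4
            assert ch.n_crossings == 8
            assert ch.mean_patch_width_um == pytest.approx(expected, abs=2 * s.spacing_um)
            assert ch.covered_fraction == pytest.approx(0.5, abs=0.02)
            assert ch.reliable

    def test_half_disc(self):
        n, radius = 128, 150.0
        green = np.where(np.arange(n) < n // 2, 200.0, 20.0)
        s = patch_stats_at_radius(_profile(green, 200.0 - green + 20, radius))
        assert s.green.n_patches == 1
        assert s.green.mean_patch_width_um == pytest.approx(np.pi * radius, rel=0.02)
        assert s.red.n_patches == 1

    def test_no_crossing_cases(self):
        n = 64
        s = patch_stats_at_radius(_profile(np.full(n, 200.0), np.full(n, 20.0)))
        assert not s.green.reliable and s.green.covered_fraction == 1.0
        assert not s.red.reliable and s.red.covered_fraction == 0.0
        assert np.isnan(s.red.mean_patch_width_um)
        assert s.green.degenerate_threshold and s.red.degenerate_threshold

    def test_invariant_crossings_patches(self, rng):
        for _ in range(20):
            g = rng.normal(100, 30, 64)
            r = rng.normal(100, 30, 64)
            s = patch_stats_at_radius(_profile(g, r))
            for ch in (s.green, s.red):
                if 0 < ch.covered_fraction < 1:
                    assert ch.n_crossings == 2 * ch.n_patches
                total = ch.mean_patch_width_um * ch.n_patches if ch.n_patches else 0.0
                assert total <= 2 * np.pi * 100.0 + s.spacing_um


class TestPatchWidthCurve:
    def test_radii_strictly_increasing_enforced(self):
        n = 64
        s1 = patch_stats_at_radius(_profile(np.full(n, 1.0), np.full(n, 1.0), 100.0))
        s2 = patch_stats_at_radius(_profile(np.full(n, 1.0), np.full(n, 1.0), 100.0))
        with pytest.raises(ValueError):
            PatchWidthCurve(stats=[s1, s2])

    def test_scaling_with_radius(self, small_sector_colony, no_coarsen_pp):
        # fixed angular pattern: mean width proportional to R
        pair, _ = small_sector_colony
        sweep = RadialSweepParams(r_start_um=150, r_end_um=300, dr_um=50)
        curve = patch_width_curve(pair, sweep, no_coarsen_pp)
        widths = curve.combined_widths_um()
        radii = curve.radii_um
        slopes = widths / radii
        np.testing.assert_allclose(slopes, 2 * np.pi / 8, rtol=0.03)

    def test_coarsening_preserves_pattern(self, small_sector_colony):
        # coarsen factor 2 shifts the center; widths must stay on the truth
        pair, gt = small_sector_colony
        sweep = RadialSweepParams(r_start_um=200, r_end_um=280, dr_um=40)
        pp = PreprocessParams(coarsen_factor=2, smooth_window_um=4)
        curve = patch_width_curve(pair, sweep, pp)
        for s in curve.stats:
            tw = truth_patch_width(gt, s.radius_um)
            assert s.green.mean_patch_width_um == pytest.approx(tw[0], rel=0.06)

    def test_to_dataframe_schema(self, small_sector_colony, small_sweep, no_coarsen_pp):
        pair, _ = small_sector_colony
        df = patch_width_curve(pair, small_sweep, no_coarsen_pp).to_dataframe()
        assert list(df.columns) == [
            "radius_um", "channel", "threshold", "n_crossings", "n_patches",
            "mean_patch_width_um", "covered_fraction", "reliable",
        ]
        assert set(df["channel"]) == {"green", "red"}


class TestAbundanceProfile:
    def test_equal_sectors_half_half(self, small_sector_colony, small_sweep, no_coarsen_pp):
        pair, _ = small_sector_colony
        df = abundance_profile(pair, small_sweep, no_coarsen_pp)
        assert (df["green_fraction"] - 0.5).abs().max() < 0.05
        assert (df["red_fraction"] - 0.5).abs().max() < 0.05

    def test_single_genotype_ring(self):
        # green-only annulus: fraction 1 vs 0, both flagged unreliable
        n = 201
        rows, cols = np.mgrid[0:n, 0:n].astype(float)
        r = np.hypot(rows - 100, cols - 100)
        green = np.where((r > 30) & (r < 70), 200.0, 200.0)  # constant high circle
        red = np.full((n, n), 20.0)
        pair = make_pair(green, red, pixel_size_um=1.0)
        sweep = RadialSweepParams(r_start_um=40, r_end_um=60, dr_um=10)
        df = abundance_profile(pair, sweep, PreprocessParams(coarsen_factor=1))
        assert (df["green_fraction"] == 1.0).all()
        assert (df["red_fraction"] == 0.0).all()
        assert not df["green_reliable"].any()
        assert not df["red_reliable"].any()
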