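import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cumulantscope import sofi, synth

from .conftest import fit_gaussian2d, quiet_sofi2d


class TestCumulantTimeseries:
    def test_constant_traces_zero(self):
        tr = np.full((100, 2), 7.0)
        assert sofi.cumulant_timeseries(tr, 2) == 0.0
        assert sofi.cumulant_timeseries(np.full((100, 4), 7.0), 4) == 0.0

    def test_bernoulli_second_and_third(self):
        # brute-force oracle: kappa2 -> p(1-p) = 0.25, kappa3 -> 0 at p = 0.5
        rng = np.random.default_rng(0)
        x = (rng.random(10**5) < 0.5).astype(float)
        k2 = sofi.cumulant_timeseries(np.column_stack([x, x]), 2)
        k3 = sofi.cumulant_timeseries(np.column_stack([x, x, x]), 3)
        assert k2 == pytest.approx(0.25, abs=0.005)
        assert abs(k3) < 0.005

    def test_bernoulli_fourth(self):
        # p(1-p)(1-6p+6p^2) = -1/8 at p = 0.5
        rng = np.random.default_rng(1)
        x = (rng.random(10**5) < 0.5).astype(float)
        k4 = sofi.cumulant_timeseries(np.column_stack([x] * 4), 4)
        assert k4 == pytest.approx(-0.125, abs=0.01)

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            sofi.cumulant_timeseries(np.zeros((100, 3)), 2)

    def test_gaussian_fourth_cumulant_vanishes(self):
        # any Gaussian signal has kappa4 = 0
        rng = np.random.default_rng(2)
        x = rng.normal(size=10**5)
        k4 = sofi.cumulant_timeseries(np.column_stack([x] * 4), 4)
        assert abs(k4) < 0.05


class TestCombinations:
    @pytest.mark.parametrize("order", [2, 3, 4])
    def test_centroids_exact(self, order):
        for (a, b), offsets in sofi.lateral_combinations(order).items():
            assert sum(o[0] for o in offsets) / order == pytest.approx(a / order)
            assert sum(o[1] for o in offsets) / order == pytest.approx(b / order)
            assert len(offsets) == order

    def test_auto_phase_is_repeated_pixel(self):
        for order in (2, 3, 4):
            assert sofi.lateral_combinations(order)[(0, 0)] == tuple([(0, 0)] * order)

    def test_order2_diagonal_tie_break(self):
        # {(0,0),(1,1)} and {(0,1),(1,0)} tie on compactness; lexicographic wins
        assert sofi.lateral_combinations(2)[(1, 1)] == ((0, 0), (1, 1))

    def test_distance_factor_order2_closed_form(self):
        # pair at distance d -> D = exp(-d^2/(4 sigma^2))
        offsets = ((0, 0), (0, 1))
        px, sigma = 100.0, 130.0
        D = sofi.distance_factor(offsets, px, 2, sigma)
        assert D == pytest.approx(np.exp(-(px**2) / (4 * sigma**2)), rel=1e-12)

    def test_distance_factor_auto_is_one(self):
        assert sofi.distance_factor(((0, 0),) * 3, 100.0, 3, 130.0) == 1.0


class TestSofi2d:
    @pytest.mark.parametrize("order", [2, 3, 4])
    def test_sqrt_n_narrowing(self, single_emitter_movie, order):
        movie, _, _ = single_emitter_movie
        sigma_wf, _, _ = fit_gaussian2d(movie.data.mean(axis=0), 100.0)
        img = quiet_sofi2d(movie, order, flatten=True)
        sigma_n, _, _ = fit_gaussian2d(img.filled(), 100.0 / order)
        assert sigma_n == pytest.approx(sigma_wf / np.sqrt(order), rel=0.05)

    def test_nonblinking_emitter_suppressed(self):
        optics = synth.OpticsModel(sigma0=130.0, pixel_size=100.0)
        em = [synth.Emitter(820.0, 790.0, epsilon=500.0, tau_on=10, tau_off=10)]
        traces_on = np.ones((2000, 1), dtype=np.uint8)  # always on, matched flux
        traces_blink = synth.simulate_blink_traces(em, 2000, seed=1)
        em_on = [synth.Emitter(820.0, 790.0, epsilon=250.0, tau_on=10, tau_off=10)]
        noise = synth.NoiseModel(poisson=True, read_sigma=0.0)
        m_on = synth.render_movie(em_on, traces_on, optics, (16, 16), noise=noise, seed=1)
        m_blink = synth.render_movie(em, traces_blink, optics, (16, 16), noise=noise, seed=1)
        peak_on = np.nanmax(np.abs(quiet_sofi2d(m_on, 2).values))
        peak_blink = np.nanmax(np.abs(quiet_sofi2d(m_blink, 2).values))
        assert peak_on < 0.05 * peak_blink

    @pytest.mark.parametrize("order", [2, 3, 4])
    def test_auto_pixel_reduces_to_timeseries(self, single_emitter_movie, order):
        movie, _, _ = single_emitter_movie
        img = quiet_sofi2d(movie, order)
        iy, ix = 8, 8
        trace = movie.data[:, iy, ix].astype(float)
        expected = sofi.cumulant_timeseries(np.column_stack([trace] * order), order)
        assert img.values[order * iy, order * ix] == pytest.approx(expected, rel=1e-8)

    def test_output_shape_and_mask(self, single_emitter_movie):
        movie, _, _ = single_emitter_movie
        img = quiet_sofi2d(movie, 3)
        assert img.values.shape == (48, 48)
        assert not img.mask.all()  # border phases are masked
        assert np.isnan(img.values[~img.mask]).all()
        assert np.isfinite(img.values[img.mask]).all()

    def test_grid_spacing(self, single_emitter_movie):
        movie, _, _ = single_emitter_movie
        for n in (2, 3, 4):
            assert quiet_sofi2d(movie, n).grid_spacing == pytest.approx(100.0 / n)

    def test_brightness_scaling_epsilon_to_the_n(self):
        # scaling emitter brightness by c scales the order-n image by c^n
        optics = synth.OpticsModel(sigma0=130.0, pixel_size=100.0)
        tr = synth.simulate_blink_traces([synth.Emitter(800, 800)], 2000, seed=5)
        imgs = {}
        for eps in (100.0, 200.0):
            em = [synth.Emitter(800.0, 800.0, epsilon=eps, tau_on=3, tau_off=12)]
            m = synth.render_movie(em, tr, optics, (16, 16), noise=None, seed=5)
            imgs[eps] = quiet_sofi2d(m, 3).filled()
        ratio = np.nanmax(np.abs(imgs[200.0])) / np.nanmax(np.abs(imgs[100.0]))
        assert ratio == pytest.approx(2**3, rel=1e-6)

    def test_additivity_over_independent_emitters(self):
        optics = synth.OpticsModel(sigma0=130.0, pixel_size=100.0)
        e1 = synth.Emitter(700.0, 800.0, epsilon=300.0, tau_on=4, tau_off=8)
        e2 = synth.Emitter(1000.0, 800.0, epsilon=300.0, tau_on=4, tau_off=8)
        T = 20000
        tr = synth.simulate_blink_traces([e1, e2], T, seed=6)
        m12 = synth.render_movie([e1, e2], tr, optics, (16, 16), noise=None, seed=6)
        m1 = synth.render_movie([e1], tr[:, :1], optics, (16, 16), noise=None, seed=6)
        m2 = synth.render_movie([e2], tr[:, 1:], optics, (16, 16), noise=None, seed=6)
        k12 = quiet_sofi2d(m12, 2).filled()
        ksum = quiet_sofi2d(m1, 2).filled() + quiet_sofi2d(m2, 2).filled()
        scale = np.abs(k12).max()
        assert np.abs(k12 - ksum).max() < 0.05 * scale

    def test_odd_order_null_at_half_duty(self):
        # p = 0.5 -> third-cumulant expectation is 0; a single noise-free
        # realization is (random scalar) x PSF^3, so the null shows up across
        # independent realizations, not across pixels
        optics = synth.OpticsModel(sigma0=130.0, pixel_size=100.0)
        em = [synth.Emitter(620.0, 590.0, epsilon=100.0, tau_on=10, tau_off=10)]
        peaks = []
        for seed in range(30):
            tr = synth.simulate_blink_traces(em, 500, seed=seed)
            m = synth.render_movie(em, tr, optics, (12, 12), noise=None, seed=seed)
            img = quiet_sofi2d(m, 3)
            peaks.append(img.values[3 * 5, 3 * 6])  # auto pixel at the emitter
        peaks = np.array(peaks)
        se = peaks.std(ddof=1) / np.sqrt(len(peaks))
        assert abs(peaks.mean()) < 3 * se

    def test_invalid_order(self, single_emitter_movie):
        movie, _, _ = single_emitter_movie
        with pytest.raises(ValueError):
            sofi.sofi2d(movie, 5)

    def test_flatten_requires_sigma_without_optics(self):
        movie = synth.BlinkMovie(data=np.random.default_rng(0).random((120, 8, 8)))
        with pytest.raises(ValueError, match="sigma"):
            sofi.sofi2d(movie, 2, flatten=True)


class TestFlatten:
    def test_flatten_matches_inline_flattening(self, single_emitter_movie):
        movie, _, _ = single_emitter_movie
        raw = quiet_sofi2d(movie, 2)
        inline = quiet_sofi2d(movie, 2, flatten=True)
        post = sofi.flatten(raw, sigma=130.0)
        np.testing.assert_allclose(post.filled(), inline.filled(), rtol=1e-12)

    def test_double_flatten_rejected(self, single_emitter_movie):
        movie, _, _ = single_emitter_movie
        img = quiet_sofi2d(movie, 2, flatten=True)
        with pytest.raises(ValueError, match="already"):
            sofi.flatten(img, sigma=130.0)

    def test_auto_pixels_unchanged(self, single_emitter_movie):
        movie, _, _ = single_emitter_movie
        raw = quiet_sofi2d(movie, 2)
        flat = sofi.flatten(raw, sigma=130.0)
        np.testing.assert_array_equal(raw.values[::2, ::2], flat.values[::2, ::2])

    def test_checkerboard_suppression(self):
        # uniform emitter field, noise-free (shot noise adds a physical
        # auto-pixel offset flattening cannot remove): flattening reduces the
        # real/virtual pixel-phase amplitude difference by >= 10x
        rng = np.random.default_rng(12)
        px, s0 = 100.0, 130.0
        ny = nx = 32
        optics = synth.OpticsModel(sigma0=s0, pixel_size=px)
        margin = 5 * s0
        em = [
            synth.Emitter(
                float(rng.uniform(margin, nx * px - margin)),
                float(rng.uniform(margin, ny * px - margin)),
                epsilon=300.0, tau_on=3, tau_off=9,
            )
            for _ in range(80)
        ]
        tr = synth.simulate_blink_traces(em, 2000, seed=12)
        movie = synth.render_movie(em, tr, optics, (ny, nx), noise=None, seed=12)
        raw = quiet_sofi2d(movie, 2)
        flat = sofi.flatten(raw, sigma=s0)

        def checkerboard(img):
            v = img.values[12:52, 12:52]
            return abs(np.nanmean(v[::2, ::2]) - np.nanmean(v[1::2, 1::2]))

        assert checkerboard(flat) < checkerboard(raw) / 10


class TestSofi3d:
    def test_plane_count_8_planes_order3(self, multiplane_movie):
        movie, _ = multiplane_movie
        vol = sofi.sofi3d(movie, 3)
        assert vol.values.shape[0] == 22

    @given(order=st.sampled_from([2, 3, 4]), P=st.integers(2, 8))
    @settings(max_examples=21, deadline=None)
    def test_plane_count_law(self, order, P):
        # brute-force enumeration of adjacent-plane multisets
        centroids = set()
        for p in range(P):
            for k in range(order + 1):
                if p + 1 >= P and k > 0:
                    continue
                centroids.add(round((p * (order - k) + (p + 1) * k) / order, 9))
        assert len(centroids) == sofi.n_output_planes(order, P) == order * (P - 1) + 1

    def test_output_plane_spacing(self, multiplane_movie):
        movie, _ = multiplane_movie
        vol = sofi.sofi3d(movie, 3)
        assert vol.plane_spacing_out == pytest.approx(350.0 / 3)

    def test_two_planes_order2_gives_three(self):
        optics = synth.OpticsModel(sigma0=130.0, pixel_size=100.0, n_planes=2)
        em = [synth.Emitter(600.0, 600.0, z=0.0, tau_on=4, tau_off=4)]
        tr = synth.simulate_blink_traces(em, 200, seed=0)
        movie = synth.render_movie(em, tr, optics, (12, 12), noise=None, seed=0)
        assert sofi.sofi3d(movie, 2).values.shape[0] == 3

    def test_axial_profile_peaks_at_emitter_plane(self, multiplane_movie):
        movie, _ = multiplane_movie  # emitter on physical plane 2
        vol = sofi.sofi3d(movie, 3)
        profile = np.nanmax(np.abs(vol.values), axis=(1, 2))
        assert np.argmax(profile) == 3 * 2

    def test_single_plane_rejected(self, single_emitter_movie):
        movie, _, _ = single_emitter_movie
        with pytest.raises(ValueError, match="sofi2d"):
            sofi.sofi3d(
                synth.BlinkMovie(data=movie.data[:, None], optics=movie.optics), 3
            )


def test_combination_centroid_uniqueness():
    # every lateral phase has exactly one canonical combination per order
    for order in (2, 3, 4):
        combos = sofi.lateral_combinations(order)
        assert set(combos) == set(itertools.product(range(order), repeat=2))
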