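"""Meshwork periodicity: densities, comb fits, spectra, segment statistics."""

import numpy as np
import pytest

from parcortex.meshwork import (ContourTrace, DensityCurve, SegmentTrace,
                                contour_lengths, edge_enhance,
                                fit_gaussian_profile, fit_k_gaussians,
                                length_density, peak_interval,
                                segment_length_stats, segment_width_fwhm,
                                spectral_periodicity, FWHM_PER_SIGMA)
from parcortex.synthetic import (make_comb_lengths, make_cross_profile,
                                 make_meshwork_image)


class TestEdgeEnhance:
    def test_constant_image_gives_zero_map(self):
        assert np.all(edge_enhance(np.full((30, 30), 7.0)) == 0)

    def test_vertical_step_peaks_on_step(self):
        img = np.zeros((20, 20))
        img[:, 10:] = 1.0
        edges = edge_enhance(img)
        assert np.argmax(edges.sum(axis=0)) in (9, 10)

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError, match="2-D"):
            edge_enhance(np.zeros((4, 4, 3)))

    def test_lattice_edges_coincide_with_truth_mask(self):
        img, _, _ = make_meshwork_image(0.4, 0.053, 0.1, noise_sd=0.05, seed=5)
        edges = edge_enhance(img)
        truth_mask = make_meshwork_image(0.4, 0.053, 0.1, 0.0, seed=5)[0] > 0.5
        from skimage.morphology import dilation

        em = edges > 0.25 * edges.max()
        iou = (em & dilation(truth_mask)).sum() / (em | truth_mask).sum()
        assert iou > 0.7


class TestContourLengths:
    def test_straight_and_l_shaped_polylines(self):
        straight = ContourTrace(np.array([[0.0, 0.0], [0.3, 0.0]]))
        bent = ContourTrace(np.array([[0.0, 0.0], [0.3, 0.0], [0.3, 0.4]]))
        assert contour_lengths([straight, bent]) == pytest.approx([0.3, 0.7])

    def test_rigid_motion_invariance(self, rng):
        pts = rng.uniform(0, 5, (6, 2))
        phi = 1.1
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        moved = pts @ rot.T + [3.0, -1.0]
        assert ContourTrace(moved).arc_length_um == pytest.approx(
            ContourTrace(pts).arc_length_um
        )

    def test_single_point_trace_rejected(self):
        with pytest.raises(ValueError, match="2 points"):
            ContourTrace(np.array([[0.0, 0.0]]))

    def test_noiseless_lattice_lengths_equal_pitch(self):
        _, polys, _ = make_meshwork_image(0.4, 0.053, 0.1, 0.0, seed=1)
        lengths = contour_lengths([ContourTrace(p) for p in polys])
        assert np.allclose(lengths, 0.4, atol=0.053)


class TestLengthDensity:
    def test_integral_is_one(self, rng):
        lengths = rng.gamma(4.0, 0.1, 300)
        d = length_density(lengths)
        assert np.trapezoid(d.density, d.grid) == pytest.approx(1.0, abs=1e-3)

    def test_single_gaussian_mode_at_mean(self, rng):
        lengths = rng.normal(1.5, 0.2, 1000)
        d = length_density(lengths)
        mode = d.grid[np.argmax(d.density)]
        assert abs(mode - 1.5) < 3 * d.step

    def test_comb_sample_has_local_maxima_near_multiples(self):
        lengths, _ = make_comb_lengths(2000, 0.4, 0.05, k=7, seed=3)
        d = length_density(lengths, bandwidth_um=0.04)
        y = d.density
        modes = d.grid[
            [i for i in range(1, y.size - 1) if y[i] > y[i - 1] and y[i] > y[i + 1]]
        ]
        hits = sum(np.min(np.abs(modes - 0.4 * k)) < 0.08 for k in range(1, 8))
        assert hits >= 5

    def test_too_few_lengths_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            length_density(np.ones(5) + np.arange(5))


class TestCombFit:
    def test_exact_seven_gaussian_density_recovered(self):
        grid = np.linspace(0, 3.2, 512)
        mus = 0.4 * np.arange(1, 8)
        y = sum(np.exp(-0.5 * ((grid - m) / 0.05) ** 2) for m in mus)
        y /= np.trapezoid(y, grid)
        d = DensityCurve(grid, y, bandwidth_um=0.05)
        fit = fit_k_gaussians(d, k=7, seed=0)
        assert np.allclose(fit.means_um, mus, atol=1e-3)
        assert fit.peak_interval_mean_um == pytest.approx(0.4, abs=1e-3)

    def test_single_gaussian_exact_via_profile_fit(self):
        x = np.linspace(-1, 1, 201)
        y = 2.0 * np.exp(-0.5 * (x / 0.3) ** 2)
        g = fit_gaussian_profile(x, y, baseline=False)
        assert g.amplitude == pytest.approx(2.0, abs=1e-6)
        assert g.sd == pytest.approx(0.3, abs=1e-6)

    def test_k_below_two_rejected(self):
        d = DensityCurve(np.linspace(0, 1, 64), np.ones(64), 0.1)
        with pytest.raises(ValueError, match="k >= 2"):
            fit_k_gaussians(d, k=1)

    def test_spacing_recovery_over_seeds(self):
        ok = 0
        for seed in range(1, 11):
            lengths, _ = make_comb_lengths(754, 0.38, 0.06 * 0.38, k=7, seed=seed)
            fit = fit_k_gaussians(length_density(lengths), k=7, seed=seed)
            ok += abs(fit.peak_interval_mean_um - 0.38) / 0.38 <= 0.10
        assert ok >= 9


class TestPeakInterval:
    def test_arithmetic_means(self):
        class F:
            means_um = np.array([0.4, 0.8, 1.2])

        mean, sd = peak_interval(F())
        assert mean == pytest.approx(0.4, abs=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_constructed_comb_at_038(self):
        class F:
            means_um = 0.38 * np.arange(1, 8)

        assert peak_interval(F())[0] == pytest.approx(0.38)

    def test_duplicate_means_rejected(self):
        class F:
            means_um = np.array([0.4, 0.4, 0.8])

        with pytest.raises(ValueError, match="distinct"):
            peak_interval(F())


class TestSpectrum:
    @staticmethod
    def _cosine_density(period=0.42):
        x = np.linspace(0, 3.0, 512)
        y = np.exp(-0.5 * ((x - 1.5) / 0.8) ** 2) * (
            1 + 0.3 * np.cos(2 * np.pi * x / period)
        )
        y /= np.trapezoid(y, x)
        return DensityCurve(x, y, bandwidth_um=0.05)

    def test_cosine_modulation_frequency_within_one_bin(self):
        d = self._cosine_density(0.42)
        sp = spectral_periodicity(d)
        bin_width = sp.frequencies[1] - sp.frequencies[0]
        assert abs(sp.major_frequency_um_inv - 1 / 0.42) <= bin_width
        assert sp.periodic
        assert sp.implied_interval_um == pytest.approx(
            1 / sp.major_frequency_um_inv
        )

    def test_single_gaussian_flagged_aperiodic(self):
        x = np.linspace(0, 3.0, 512)
        y = np.exp(-0.5 * ((x - 1.5) / 0.4) ** 2)
        y /= np.trapezoid(y, x)
        sp = spectral_periodicity(DensityCurve(x, y, bandwidth_um=0.05))
        assert not sp.periodic

    def test_non_uniform_grid_rejected(self):
        grid = np.concatenate([np.linspace(0, 1, 32), np.linspace(1.1, 3, 40)])
        with pytest.raises(ValueError, match="uniform"):
            DensityCurve(grid, np.ones(72), 0.1)

    def test_spectral_and_comb_fit_agree_on_comb_density(self):
        lengths, _ = make_comb_lengths(754, 0.40, 0.06 * 0.40, k=7, seed=4)
        d = length_density(lengths, bandwidth_um=0.06)
        fit = fit_k_gaussians(d, k=7, seed=4)
        sp = spectral_periodicity(d)
        assert sp.periodic
        assert sp.implied_interval_um == pytest.approx(
            fit.peak_interval_mean_um, rel=0.15
        )


class TestSegments:
    def test_straight_length(self):
        seg = SegmentTrace((0.0, 0.0), (0.39, 0.0))
        assert seg.straight_length_um == pytest.approx(0.39)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            SegmentTrace((1.0, 1.0), (1.0, 1.0))

    def test_stats_on_truncated_gaussian_sample(self, rng):
        lengths = rng.normal(0.39, 0.09, 194)
        lengths = lengths[lengths > 0]
        segs = [SegmentTrace((0, 0), (l, 0)) for l in lengths]
        stats = segment_length_stats(segs)
        assert stats.mean_um == pytest.approx(0.39, abs=0.02)
        assert stats.n == len(segs)

    def test_fwhm_noiseless_analytic(self):
        x, y, _ = make_cross_profile(0.2355, 1.0, 0.0, 0.01, 0.0, seed=1)
        assert segment_width_fwhm(x, y) == pytest.approx(0.2355, abs=1e-4)
        # sigma = 0.1 gives FWHM 2*sqrt(2 ln 2)*0.1
        assert 0.1 * FWHM_PER_SIGMA == pytest.approx(0.23548, abs=1e-5)

    def test_fwhm_with_baseline_noiseless(self):
        x, y, _ = make_cross_profile(0.23, 1.0, 0.2, 0.02, 0.0, seed=1)
        assert segment_width_fwhm(x, y) == pytest.approx(0.23, rel=0.01)

    def test_fwhm_noise_study(self):
        good = 0
        for seed in range(100):
            x, y, _ = make_cross_profile(0.23, 1.0, 0.2, 0.02, 0.05, seed=seed)
            try:
                w = segment_width_fwhm(x, y)
            except (ValueError, RuntimeError):
                continue
            good += abs(w - 0.23) / 0.23 <= 0.10
        assert good >= 95

    def test_flat_profile_rejected(self):
        x = np.linspace(-1, 1, 21)
        with pytest.raises(ValueError, match="peak"):
            segment_width_fwhm(x, np.ones_like(x))
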