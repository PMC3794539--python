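import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter

import srrkit as sk
from srrkit.metrics import (
    LOGISTIC_RISE_CONSTANT,
    BoxROI,
    LineProfile,
    SigmoidFit,
    sigmoid_edge_model,
)


def volume_with_rois(signal=100.0, noise_sd=10.0, seed=0):
    rng = np.random.default_rng(seed)
    data = np.zeros((24, 24, 24))
    data[:9, :9, :9] = signal
    data[12:21, 12:21, 12:21] = rng.normal(0.0, noise_sd, (9, 9, 9))
    vol = sk.Volume(data, spacing=(0.1,) * 3)
    return vol, BoxROI((0, 0, 0)), BoxROI((12, 12, 12))


class TestSNRandCNR:
    def test_snr_direct_computation(self):
        vol, sig, noi = volume_with_rois(signal=100.0, noise_sd=10.0)
        measured_sd = noi.extract(vol).std()
        assert sk.compute_snr(vol, sig, noi) == pytest.approx(100.0 / measured_sd)

    def test_snr_zero_mean_signal(self):
        vol, _, noi = volume_with_rois()
        assert abs(sk.compute_snr(vol, noi, noi)) < 0.2

    def test_snr_zero_noise_is_error_not_inf(self):
        vol, sig, _ = volume_with_rois()
        with pytest.raises(ValueError, match="undefined"):
            sk.compute_snr(vol, sig, BoxROI((0, 12, 0)))

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_snr_scale_invariant(self, scale):
        vol, sig, noi = volume_with_rois()
        scaled = vol.with_data(vol.data * scale)
        assert sk.compute_snr(scaled, sig, noi) == pytest.approx(
            sk.compute_snr(vol, sig, noi)
        )

    def test_cnr_hand_computed(self):
        rng = np.random.default_rng(1)
        data = np.zeros((20, 20, 20))
        data[:9, :9, :9] = 80.0 + rng.normal(0, 5.0, (9, 9, 9))
        data[10:19, 10:19, 10:19] = 20.0 + rng.normal(0, 10.0, (9, 9, 9))
        vol = sk.Volume(data, spacing=(0.1,) * 3)
        hi, lo = BoxROI((0, 0, 0)), BoxROI((10, 10, 10))
        a, b = hi.extract(vol), lo.extract(vol)
        expected = abs(a.mean() - b.mean()) / max(a.std(), b.std())
        assert sk.compute_cnr(vol, hi, lo) == pytest.approx(expected)
        # swapping high and low leaves the value unchanged
        assert sk.compute_cnr(vol, lo, hi) == pytest.approx(expected)

    def test_cnr_identical_rois_is_zero(self):
        vol, _, noi = volume_with_rois()
        assert sk.compute_cnr(vol, noi, noi) == 0.0

    def test_cnr_shift_invariant(self):
        vol, sig, noi = volume_with_rois()
        shifted = vol.with_data(vol.data + 37.0)
        assert sk.compute_cnr(shifted, sig, noi) == pytest.approx(
            sk.compute_cnr(vol, sig, noi)
        )

    def test_roi_outside_volume_rejected(self):
        vol, *_ = volume_with_rois()
        with pytest.raises(ValueError):
            BoxROI((20, 0, 0)).extract(vol)


class TestLineProfile:
    def test_constant_volume_gives_constant_profile(self):
        vol = sk.Volume(np.full((16, 16, 16), 3.5), spacing=(0.2,) * 3)
        prof = sk.extract_line_profile(vol, (0.4, 0.4, 0.2), (0.4, 0.4, 2.8), 50)
        np.testing.assert_allclose(prof.values, 3.5, atol=1e-12)

    def test_axis_aligned_profile_hits_voxel_centres(self):
        rng = np.random.default_rng(2)
        vol = sk.Volume(rng.normal(size=(8, 8, 8)), spacing=(0.5,) * 3)
        prof = sk.extract_line_profile(vol, (1.0, 1.5, 0.0), (1.0, 1.5, 3.5), 8)
        np.testing.assert_allclose(prof.values, vol.data[2, 3, :], atol=1e-12)

    def test_coordinates_in_hr_pixels(self):
        vol = sk.Volume(np.zeros((16, 16, 16)), spacing=(0.2,) * 3)
        prof = sk.extract_line_profile(vol, (0, 0, 0), (0, 0, 2.0), 11)
        assert prof.x_pixels[-1] == pytest.approx(10.0)


class TestSigmoidFit:
    def make_profile(self, a1, a2, a3, a4, length=80.0, noise=0.0, seed=0):
        # 0.25-pixel sampling, the package's supersampled edge-fit convention
        x = np.arange(0.0, length, 0.25)
        v = sigmoid_edge_model(x, a1, a2, a3, a4)
        if noise:
            v = v + np.random.default_rng(seed).normal(0, noise, x.size)
        return LineProfile(x_pixels=x, values=v)

    def test_noiseless_recovery_and_unit_edge_width(self):
        prof = self.make_profile(0.0, 1.0, 4.4, 40.0)
        fit = sk.fit_sigmoid_edge(prof)
        assert fit.converged
        assert fit.a3 == pytest.approx(4.4, rel=1e-6)
        assert sk.edge_width_pixels(fit) == pytest.approx(1.0, rel=1e-6)

    def test_descending_profile_flipped(self):
        prof = self.make_profile(0.0, 1.0, 4.4, 40.0)
        rev = LineProfile(x_pixels=prof.x_pixels, values=prof.values[::-1].copy())
        fit = sk.fit_sigmoid_edge(rev)
        assert fit.flipped
        assert fit.a3 > 0
        assert fit.a3 == pytest.approx(4.4, rel=1e-4)

    def test_noisy_recovery_median_within_5pct(self):
        errors = []
        for seed in range(10):
            prof = self.make_profile(0.0, 1.0, 4.4, 40.0, noise=0.02, seed=seed)
            fit = sk.fit_sigmoid_edge(prof)
            if fit.converged:
                errors.append(abs(fit.a3 - 4.4) / 4.4)
        assert np.median(errors) < 0.05

    def test_discrete_step_width_at_most_two_pixels(self):
        v = np.zeros(40)
        v[20:] = 1.0
        fit = sk.fit_sigmoid_edge(v)
        assert fit.converged
        assert sk.edge_width_pixels(fit) <= 2.0

    def test_flat_profile_is_error(self):
        with pytest.raises(ValueError, match="flat"):
            sk.fit_sigmoid_edge(np.ones(20))

    def test_too_few_samples_is_error(self):
        with pytest.raises(ValueError):
            sk.fit_sigmoid_edge(np.arange(5.0))


class TestEdgeWidth:
    def test_paper_constant_values(self):
        assert sk.edge_width_pixels(SigmoidFit(0, 1, 4.4, 0)) == pytest.approx(1.0)
        assert sk.edge_width_pixels(SigmoidFit(0, 1, 2.2, 0)) == pytest.approx(2.0)

    def test_rise_constant_matches_closed_form(self):
        # analytic 10-90% rise of the logistic is 2 ln 9 per unit a3
        ratio = (2.0 * np.log(9.0)) / LOGISTIC_RISE_CONSTANT
        assert 0.998 <= ratio <= 1.0

    @given(a3=st.floats(0.1, 50.0), factor=st.floats(1.01, 10.0))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_width_antitone_in_slope(self, a3, factor):
        w1 = sk.edge_width_pixels(SigmoidFit(0, 1, a3, 0))
        w2 = sk.edge_width_pixels(SigmoidFit(0, 1, a3 * factor, 0))
        assert w2 < w1


class TestMeanEdgeWidth:
    def test_mean_is_arithmetic_mean_of_per_profile_widths(self):
        # rows whose x-profiles are sigmoids of width 2, 3 and 4 px (gentle
        # enough that linear resampling barely widens them)
        n = 64
        x = np.arange(n, dtype=float)
        data = np.zeros((3, 4, n))
        for i, a3 in enumerate([4.4 / 2.0, 4.4 / 3.0, 4.4 / 4.0]):
            data[i, :, :] = sigmoid_edge_model(x, 0.0, 1.0, a3, n / 2)[None, :]
        vol = sk.Volume(data, spacing=(1.0,) * 3)
        segments = [((i, 1.0, 0.0), (i, 1.0, n - 1.0)) for i in range(3)]
        summary = sk.mean_edge_width(vol, segments, n=3)
        assert summary.n_converged == 3
        assert summary.mean_width_pixels == pytest.approx(np.mean(summary.widths))
        # linear resampling of the discrete profile widens each edge by a
        # fraction of a pixel, so the absolute check is loose
        assert summary.mean_width_pixels == pytest.approx(3.0, rel=0.10)

    def test_width_increases_with_blur(self, biological_64):
        vol, layout = biological_64
        mild = vol.with_data(gaussian_filter(vol.data, 2.0 / 2.355))
        heavy = vol.with_data(gaussian_filter(vol.data, 4.0 / 2.355))
        w_mild = sk.mean_edge_width(mild, layout.edge_segments, n=20)
        w_heavy = sk.mean_edge_width(heavy, layout.edge_segments, n=20)
        assert w_heavy.mean_width_pixels > w_mild.mean_width_pixels


class TestTubeModulation:
    def test_truth_phantom_nearly_full_contrast(self, small_resolution_volume):
        spec, vol = small_resolution_volume
        layout = sk.resolution_phantom_layout(spec)
        prof = sk.extract_line_profile(
            vol, layout.profile_start_mm, layout.profile_end_mm, 400
        )
        assert sk.tube_modulation(prof, spec.n_tubes) > 0.9

    def test_constant_profile_scores_zero(self):
        assert sk.tube_modulation(np.full(100, 5.0), 5) == 0.0

    def test_heavy_blur_merges_minima_to_zero(self, small_resolution_volume):
        spec, vol = small_resolution_volume
        layout = sk.resolution_phantom_layout(spec)
        blurred = vol.with_data(gaussian_filter(vol.data, 8.0))
        prof = sk.extract_line_profile(
            blurred, layout.profile_start_mm, layout.profile_end_mm, 400
        )
        assert sk.tube_modulation(prof, spec.n_tubes) == 0.0
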