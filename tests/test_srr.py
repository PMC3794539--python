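import warnings

import numpy as np
import pytest

import srrkit as sk
from srrkit.acquisition import LRStack


def identity_geometry():
    return sk.StackGeometry(kind="shifted", shift_mm=0.0, slice_axis=0)


def constant_stack(value, n_slices=4, thickness=0.8, spacing=0.2):
    ar = thickness / spacing
    centers = (np.arange(n_slices) + 0.5) * ar - 0.5
    return LRStack(
        data=np.full((n_slices, 6, 6), float(value)),
        geometry=identity_geometry(),
        model=sk.AcquisitionModel(inplane_spacing=spacing, slice_thickness=thickness),
        slice_positions=centers * spacing,
        hr_shape=(int(n_slices * ar), 6, 6),
        hr_spacing=spacing,
    )


@pytest.fixture(scope="module")
def orthogonal_noiseless(small_resolution_volume):
    spec, hr = small_resolution_volume
    model = sk.AcquisitionModel(inplane_spacing=0.2, slice_thickness=0.8)
    plan = sk.plan_orthogonal(0.8, 0.2)
    stacks = [
        sk.simulate_lr_stack(hr, g, model, fill=spec.background_intensity)
        for g in plan.geometries
    ]
    return hr, stacks, spec.background_intensity


class TestInitialize:
    def test_single_identity_stack_is_passed_through(self):
        rng = np.random.default_rng(0)
        vol = sk.Volume(rng.normal(50, 5, (12, 8, 8)), spacing=(0.2,) * 3)
        model = sk.AcquisitionModel(inplane_spacing=0.2, slice_thickness=0.2,
                                    blur_fwhm=0.01)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack = sk.simulate_lr_stack(vol, identity_geometry(), model)
        init = sk.ibp_initialize([stack])
        np.testing.assert_allclose(init.data, vol.data, atol=1e-12)

    def test_mean_of_constant_stacks(self):
        init = sk.ibp_initialize([constant_stack(4.0), constant_stack(6.0)])
        np.testing.assert_allclose(init.data, 5.0, atol=1e-12)

    def test_averaging_reduces_error_vs_any_single_view(self, smooth_blob_48):
        # on an isotropic blob every view errs comparably, so the three-view
        # mean must beat each individual upsampled view
        model = sk.AcquisitionModel(inplane_spacing=0.2, slice_thickness=0.8)
        plan = sk.plan_orthogonal(0.8, 0.2)
        stacks = [
            sk.simulate_lr_stack(smooth_blob_48, g, model) for g in plan.geometries
        ]
        init = sk.ibp_initialize(stacks)
        rms_init = np.sqrt(np.mean((init.data - smooth_blob_48.data) ** 2))
        for s in stacks:
            single = sk.ibp_initialize([s])
            rms_single = np.sqrt(np.mean((single.data - smooth_blob_48.data) ** 2))
            assert rms_init < rms_single

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            sk.ibp_initialize([])


class TestSimulateAndResidual:
    def test_forward_model_consistency(self, orthogonal_noiseless):
        hr, stacks, bg = orthogonal_noiseless
        simulated = sk.ibp_simulate(hr, stacks, fill=bg)
        for obs, sim in zip(stacks, simulated):
            np.testing.assert_allclose(sim.data, obs.data, atol=1e-9)

    def test_linearity(self, orthogonal_noiseless):
        hr, stacks, bg = orthogonal_noiseless
        doubled = hr.with_data(2.0 * hr.data)
        sim1 = sk.ibp_simulate(hr, stacks, fill=0.0)
        sim2 = sk.ibp_simulate(doubled, stacks, fill=0.0)
        for a, b in zip(sim1, sim2):
            np.testing.assert_allclose(b.data, 2.0 * a.data, atol=1e-9)

    def test_constant_estimate_gives_constant_stacks(self):
        est = sk.Volume(np.full((16, 6, 6), 3.0), spacing=(0.2,) * 3)
        sim = sk.ibp_simulate(est, [constant_stack(0.0)], fill=3.0)[0]
        np.testing.assert_allclose(sim.data, 3.0, atol=1e-12)

    def test_residual_zero_for_identical(self):
        s = constant_stack(5.0)
        assert sk.ibp_residual([s], [s]) == 0.0

    def test_residual_constant_offset_max_abs(self):
        a, b = constant_stack(5.0), constant_stack(2.5)
        assert sk.ibp_residual([a], [b], "max_abs") == pytest.approx(2.5)

    def test_residual_rms_matches_brute_force(self):
        rng = np.random.default_rng(3)
        obs = constant_stack(0.0)
        sim = obs.with_data(rng.normal(size=obs.data.shape))
        expected = float(np.sqrt(np.mean((obs.data - sim.data) ** 2)))
        assert sk.ibp_residual([obs], [sim], "rms") == pytest.approx(expected, abs=1e-15)

    def test_residual_list_mismatch(self):
        with pytest.raises(ValueError):
            sk.ibp_residual([constant_stack(1.0)], [])


class TestUpdate:
    def test_zero_difference_is_fixed_point(self):
        est = sk.Volume(np.full((16, 6, 6), 7.0), spacing=(0.2,) * 3)
        s = constant_stack(1.0)
        out = sk.ibp_update(est, [s], [s])
        np.testing.assert_array_equal(out.data, est.data)

    def test_constant_difference_backprojected(self):
        est = sk.Volume(np.zeros((16, 6, 6)), spacing=(0.2,) * 3)
        out = sk.ibp_update(est, [constant_stack(3.0)], [constant_stack(1.0)])
        np.testing.assert_allclose(out.data, 2.0, atol=1e-12)

    def test_two_stack_update_matches_manual_oracle(self):
        rng = np.random.default_rng(7)
        est = sk.Volume(rng.normal(10, 1, (16, 6, 6)), spacing=(0.2,) * 3)
        obs = [
            constant_stack(0.0).with_data(rng.normal(size=(4, 6, 6))),
            constant_stack(0.0).with_data(rng.normal(size=(4, 6, 6))),
        ]
        sim = [
            obs[0].with_data(rng.normal(size=(4, 6, 6))),
            obs[1].with_data(rng.normal(size=(4, 6, 6))),
        ]
        out = sk.ibp_update(est, obs, sim)
        manual = est.data.copy()
        correction = np.zeros_like(manual)
        for o, s in zip(obs, sim):
            diff = o.with_data(o.data - s.data)
            correction += sk.upsample_stack(diff).data
        manual += correction / 2.0
        np.testing.assert_allclose(out.data, manual, atol=1e-12)


class TestReconstruct:
    def test_degenerate_identity_converges_immediately(self):
        rng = np.random.default_rng(1)
        vol = sk.Volume(rng.normal(50, 5, (12, 8, 8)), spacing=(0.2,) * 3)
        model = sk.AcquisitionModel(inplane_spacing=0.2, slice_thickness=0.2,
                                    blur_fwhm=0.01)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack = sk.simulate_lr_stack(vol, identity_geometry(), model)
            recon, trace = sk.ibp_reconstruct([stack])
        assert trace.converged
        assert trace.iterations_run == 1
        assert trace.residuals[0] < 1e-9
        np.testing.assert_allclose(recon.data, vol.data, atol=1e-9)

    def test_improves_over_initialization(self, orthogonal_noiseless):
        hr, stacks, bg = orthogonal_noiseless
        cfg = sk.IBPConfig(fill=bg)
        recon, trace = sk.ibp_reconstruct(stacks, cfg)
        init = sk.ibp_initialize(stacks, cfg)
        rms_final = np.sqrt(np.mean((recon.data - hr.data) ** 2))
        rms_init = np.sqrt(np.mean((init.data - hr.data) ** 2))
        assert rms_final < rms_init

    def test_residual_decreases_on_noiseless_fixture(self, orthogonal_noiseless):
        hr, stacks, bg = orthogonal_noiseless
        _, trace = sk.ibp_reconstruct(stacks, sk.IBPConfig(fill=bg))
        assert len(trace.residuals) >= 5
        assert trace.residuals[4] <= trace.residuals[0]

    def test_deterministic(self, orthogonal_noiseless):
        _, stacks, bg = orthogonal_noiseless
        cfg = sk.IBPConfig(fill=bg, max_iterations=5)
        a, _ = sk.ibp_reconstruct(stacks, cfg)
        b, _ = sk.ibp_reconstruct(stacks, cfg)
        np.testing.assert_array_equal(a.data, b.data)

    def test_trace_records_both_norms(self, orthogonal_noiseless):
        _, stacks, bg = orthogonal_noiseless
        _, trace = sk.ibp_reconstruct(stacks, sk.IBPConfig(fill=bg, max_iterations=3))
        assert len(trace.residuals_max_abs) == trace.iterations_run
        assert len(trace.residuals_rms) == trace.iterations_run
        assert all(
            r <= m + 1e-12
            for r, m in zip(trace.residuals_rms, trace.residuals_max_abs)
        )

    def test_empty_stack_list_rejected(self):
        with pytest.raises(ValueError):
            sk.ibp_reconstruct([])
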