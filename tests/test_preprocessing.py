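import numpy as np
import pytest

import utemap as u
from utemap.preprocessing import PolynomialField, fit_smooth_field


def _quadratic_mm(x, y, z):
    """A smooth field expressed in world mm, evaluable on any grid."""
    return 1.0 + 0.1 * (x / 30.0) ** 2 - 0.05 * (y / 30.0) ** 2 + 0.002 * z


def _field_volume(shape, spacing):
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    return u.VoxelVolume(_quadratic_mm(xx, yy, zz), spacing)


class TestResample:
    def test_identity_resample(self, rng):
        vol = u.VoxelVolume(rng.normal(size=(12, 10, 6)), (1, 1, 1))
        out = u.resample_to_grid(vol, vol)
        assert np.allclose(out.data, vol.data, atol=1e-12)

    def test_constant_field_restored_exactly(self):
        low = u.VoxelVolume(np.full((8, 8, 4), 3.7), (2, 2, 2))
        target = u.VoxelVolume(np.zeros((16, 16, 8)), (1, 1, 1))
        out = u.resample_to_grid(low, target)
        assert np.allclose(out.data, 3.7, atol=1e-12)

    def test_smooth_field_upsampling_error_below_one_percent(self):
        # low-res 96x96 transmit-map grid (200 mm FOV) up to the 256x256
        # imaging grid (198 mm FOV): the map's FOV covers the image's
        low = _field_volume((96, 96, 8), (200.0 / 96, 200.0 / 96, 8.0))
        target_spec = ((256, 256, 8), (198.0 / 256, 198.0 / 256, 8.0))
        target = u.VoxelVolume(np.zeros(target_spec[0]), target_spec[1])
        out = u.resample_to_grid(low, target)
        truth = _field_volume(*target_spec)
        rel = np.abs(out.data - truth.data) / np.abs(truth.data)
        assert rel.max() < 0.01

    def test_single_slice_axis_warns(self):
        low = u.VoxelVolume(np.full((8, 8, 1), 2.0), (1, 1, 5))
        target = u.VoxelVolume(np.zeros((8, 8, 4)), (1, 1, 1))
        with pytest.warns(UserWarning, match="single-voxel"):
            out = u.resample_to_grid(low, target)
        assert np.allclose(out.data, 2.0)


class TestPolynomialField:
    def test_coefficient_count_invariant(self):
        with pytest.raises(ValueError):
            PolynomialField(2, np.ones(9))  # degree 2 needs C(5,3)=10
        PolynomialField(2, np.ones(10))

    def test_constant_field_recovered_exactly(self):
        vol = u.VoxelVolume(np.full((10, 10, 5), 4.2), (1, 1, 1))
        for degree in (0, 1, 3):
            field = fit_smooth_field(vol, degree)
            assert np.allclose(field.evaluate(vol.shape), 4.2, atol=1e-9)

    def test_smoothing_gain_on_noisy_quadratic(self, rng):
        vol = _field_volume((24, 24, 12), (1, 1, 1))
        sigma = 0.02 * float(vol.data.mean())
        noisy = u.VoxelVolume(vol.data + rng.normal(0, sigma, vol.shape), vol.spacing)
        smoothed = u.smooth_field_volume(noisy, degree=2)
        rmse = np.sqrt(np.mean((smoothed.data - vol.data) ** 2))
        assert rmse < sigma / 3

    def test_insufficient_voxels_reduce_degree(self, rng):
        data = np.full((10, 10, 1), np.nan)
        data[0, :, 0] = 1.0  # 10 valid voxels, degree 3 needs 20 coefficients
        vol = u.VoxelVolume(data, (1, 1, 1))
        with pytest.warns(UserWarning, match="reduced"):
            field = fit_smooth_field(vol, 3)
        assert field.degree < 3

    def test_projection_idempotence(self, rng):
        noisy = u.VoxelVolume(rng.normal(1.0, 0.1, (12, 12, 6)), (1, 1, 1))
        once = u.smooth_field_volume(noisy, degree=3)
        twice = u.smooth_field_volume(once, degree=3)
        assert np.allclose(once.data, twice.data, atol=1e-8)


class TestDenoise:
    def test_zero_strength_is_identity(self, rng):
        vol = u.VoxelVolume(rng.normal(10, 1, (10, 10, 4)), (1, 1, 1))
        out = u.denoise(vol, 0.0)
        assert np.array_equal(out.data, vol.data)

    def test_edge_preserving_smoothing_on_phantom(self, t2_truth):
        rng = np.random.default_rng(30)
        s0 = t2_truth["s0"].data
        sigma = s0.max() / 30.0  # SNR 30 on the tube signal
        noisy_data = np.hypot(s0 + rng.normal(0, sigma, s0.shape),
                              rng.normal(0, sigma, s0.shape))
        noisy = u.VoxelVolume(noisy_data, t2_truth.grid.spacing)
        fg = u.background_mask(noisy, 0.1)
        out = u.denoise(u.apply_mask(noisy, fg), 1.0)
        tubes = t2_truth["label"].data > 0
        for tube_id in (1, 4, 7):
            sel = t2_truth["label"].data == tube_id
            assert out.data[sel].std() <= noisy.data[sel].std() / 2
            shift = abs(out.data[sel].mean() - noisy.data[sel].mean())
            assert shift / noisy.data[sel].mean() < 0.01
        assert tubes.any()

    def test_pure_noise_variance_reduced(self, rng):
        vol = u.VoxelVolume(rng.normal(0, 1, (16, 16, 8)), (1, 1, 1))
        out = u.denoise(vol, 1.0)
        assert out.data.var() < vol.data.var()

    def test_negative_strength_rejected(self, rng):
        vol = u.VoxelVolume(rng.normal(size=(4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError):
            u.denoise(vol, -1.0)


class TestSubtraction:
    def test_identical_inputs_zero(self, rng):
        vol = u.VoxelVolume(rng.normal(size=(6, 6, 3)), (1, 1, 1))
        out = u.subtraction_image(vol, vol.copy())
        assert np.all(out.data == 0)

    def test_short_t2star_tissue_is_brighter(self, protocols):
        _, p2 = protocols
        fast = u.signal_models.TissueParams(800.0, 3.0, 100.0)
        slow = u.signal_models.TissueParams(800.0, 30.0, 100.0)
        data2 = np.zeros((4, 4, 1))
        data3 = np.zeros((4, 4, 1))
        data2[:2], data3[:2] = (u.spgr_signal(fast, p2.tr, p2.fa, te)
                                for te in (p2.tes[0], p2.tes[1]))
        data2[2:], data3[2:] = (u.spgr_signal(slow, p2.tr, p2.fa, te)
                                for te in (p2.tes[0], p2.tes[1]))
        out = u.subtraction_image(
            u.VoxelVolume(data2, (1, 1, 1)), u.VoxelVolume(data3, (1, 1, 1))
        )
        assert out.data[:2].min() > out.data[2:].max()

    def test_mask_propagates(self, rng):
        a = u.VoxelVolume(rng.normal(size=(4, 4, 2)), (1, 1, 1))
        mask = np.ones(a.shape, dtype=bool)
        mask[0, 0, 0] = False
        b = u.VoxelVolume(rng.normal(size=(4, 4, 2)), (1, 1, 1), mask=mask)
        out = u.subtraction_image(a, b)
        assert not out.valid[0, 0, 0]
        assert out.valid.sum() == a.data.size - 1


class TestChainEquivalence:
    def test_noiseless_chain_equals_direct_mapping(self, t2_truth, protocols):
        """Masking and denoising a noiseless phantom must not perturb the map."""
        _, p2 = protocols
        scan = u.simulate_scan(t2_truth, p2, 0.0, seed=0)
        e0, e1 = scan["echo0"], scan["echo1"]
        direct = u.dual_echo_t2star(e0, e1, p2.tes[0], p2.tes[1]).volume
        fg = u.background_mask(e0, 0.1)
        chained = u.dual_echo_t2star(
            u.denoise(u.apply_mask(e0, fg), 1.0),
            u.denoise(u.apply_mask(e1, fg), 1.0),
            p2.tes[0],
            p2.tes[1],
        ).volume
        sel = chained.valid
        assert np.array_equal(direct.data[sel], chained.data[sel])
        assert np.array_equal(sel, direct.valid & fg.data.astype(bool))


class TestAlignmentCheck:
    def test_aligned_volumes_pass_quietly(self, rng):
        data = rng.normal(size=(24, 24, 8))
        a = u.VoxelVolume(data, (1, 1, 1))
        b = u.VoxelVolume(data + rng.normal(0, 0.01, data.shape), (1, 1, 1))
        shift = u.check_alignment(a, b)
        assert np.linalg.norm(shift) <= 0.5

    def test_shifted_volume_warns(self, rng):
        data = np.zeros((24, 24, 8))
        data[8:16, 8:16, 2:6] = 1.0
        a = u.VoxelVolume(data, (1, 1, 1))
        b = u.VoxelVolume(np.roll(data, 3, axis=0), (1, 1, 1))
        with pytest.warns(UserWarning, match="shift"):
            u.check_alignment(a, b)
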