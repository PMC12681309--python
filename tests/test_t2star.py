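import numpy as np
import pytest

import utemap as u
from utemap.signal_models import TissueParams
from utemap.t2star import EchoSeries, etsme_echo_times


def _vol(data):
    return u.VoxelVolume(np.asarray(data, dtype=float), (1, 1, 1))


def _rician(mean, sigma, rng):
    return np.hypot(mean + rng.normal(0, sigma, np.shape(mean)),
                    rng.normal(0, sigma, np.shape(mean)))


class TestDualEcho:
    def test_log_ratio_of_e(self):
        s2 = _vol(np.full((2, 2, 1), np.e))
        s3 = _vol(np.ones((2, 2, 1)))
        out = u.dual_echo_t2star(s2, s3, 0.03, 2.46)
        assert np.allclose(out.volume.data, 2.43)

    def test_inverts_forward_model(self):
        tissue = TissueParams(t1=1000.0, t2star=5.0, s0=100.0)
        s2 = _vol(np.full((3, 3, 2), u.spgr_signal(tissue, 9.24, 11.0, 0.03)))
        s3 = _vol(np.full((3, 3, 2), u.spgr_signal(tissue, 9.24, 11.0, 2.46)))
        out = u.dual_echo_t2star(s2, s3, 0.03, 2.46)
        assert np.allclose(out.volume.data, 5.0, rtol=1e-9)

    def test_equal_echoes_invalid(self):
        s2 = _vol(np.ones((2, 2, 2)))
        out = u.dual_echo_t2star(s2, s2.copy(), 0.03, 2.46)
        assert not out.volume.valid.any()

    def test_cap_clips_and_flags(self):
        # tiny decay => T2* far above the cap
        s2 = _vol(np.full((2, 2, 1), 100.0))
        s3 = _vol(np.full((2, 2, 1), 99.99))
        out = u.dual_echo_t2star(s2, s3, 0.03, 2.46, t2_cap=100.0)
        assert np.all(out.volume.data == 100.0)
        assert out.clipped.all()

    def test_grid_mismatch_raises(self):
        s2 = _vol(np.ones((2, 2, 2)))
        s3 = u.VoxelVolume(np.ones((2, 2, 3)), (1, 1, 1))
        with pytest.raises(u.volumes.GridMismatchError):
            u.dual_echo_t2star(s2, s3, 0.03, 2.46)

    def test_echo_order_precondition(self):
        s2 = _vol(np.ones((2, 2, 2)))
        with pytest.raises(ValueError):
            u.dual_echo_t2star(s2, s2, 2.46, 0.03)


class TestMonoExpFit:
    def test_exact_exponential_recovery(self):
        tes = np.array([0.03, 2.46, 4.92])
        fit = u.monoexp_fit(EchoSeries(tes, 100.0 * np.exp(-tes / 3.0)))
        assert fit.s0 == pytest.approx(100.0, rel=1e-6)
        assert fit.t2star == pytest.approx(3.0, rel=1e-6)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            u.monoexp_fit(EchoSeries([0.03, 2.46], [10.0, 5.0]))

    def test_nonpositive_samples_excluded(self):
        tes = np.array([0.03, 1.0, 2.0, 3.0])
        sig = 10.0 * np.exp(-tes / 2.0)
        sig[3] = -0.5
        fit = u.monoexp_fit(EchoSeries(tes, sig))
        assert fit.t2star == pytest.approx(2.0, rel=1e-9)

    def test_high_snr_monte_carlo_unbiased(self):
        rng = np.random.default_rng(1)
        tes = np.array([0.03, 2.46, 4.92])
        truth = 100.0 * np.exp(-tes / 5.0)
        est = np.array(
            [
                u.monoexp_fit(EchoSeries(tes, truth + rng.normal(0, 1.0, 3))).t2star
                for _ in range(1000)
            ]
        )
        se = est.std(ddof=1) / np.sqrt(est.size)
        assert abs(est.mean() - 5.0) < 3 * se

    def test_dual_echo_is_two_point_special_case(self):
        # the two-point log-linear fit passes through both samples exactly
        from utemap.t2star import _loglinear_fit

        tes = np.array([0.03, 2.46])
        sig = np.array([80.0, 30.0])
        _, t2 = _loglinear_fit(tes, sig, sig**2)
        closed = (2.46 - 0.03) / np.log(sig[0] / sig[1])
        assert float(t2) == pytest.approx(closed, rel=1e-12)


class TestMultiEchoMap:
    def test_noiseless_three_methods_agree_exactly(self, t2_truth, protocols):
        _, p2 = protocols
        scan = u.simulate_scan(t2_truth, p2, 0.0, seed=0)
        e0, e1, e2 = (scan[f"echo{i}"] for i in range(3))
        truth = t2_truth["t2star"]
        sel = truth.valid
        for vol in (
            u.dual_echo_t2star(e0, e1, p2.tes[0], p2.tes[1]).volume,
            u.dual_echo_t2star(e0, e2, p2.tes[0], p2.tes[2]).volume,
            u.multi_echo_t2star([e0, e1, e2], p2.tes).volume,
        ):
            rel = np.abs(vol.data[sel] - truth.data[sel]) / truth.data[sel]
            assert np.nanmax(rel) < 1e-6

    def test_requires_three_echoes(self):
        v = _vol(np.ones((2, 2, 2)))
        with pytest.raises(ValueError):
            u.multi_echo_t2star([v, v], [0.03, 2.46])


class TestEtsmeReference:
    @pytest.mark.parametrize("t2s", [1.5, 20.0])
    def test_noiseless_recovery(self, t2s):
        tes = etsme_echo_times()
        series = EchoSeries(tes, 50.0 * np.exp(-tes / t2s))
        assert u.etsme_reference(series) == pytest.approx(t2s, rel=1e-6)

    def test_shifted_only_restricts_samples(self):
        tes = etsme_echo_times()
        sig = 50.0 * np.exp(-tes / 2.0)
        sig[22:] = 0.4  # late echoes replaced by a noise floor
        series = EchoSeries(tes, sig)
        assert u.etsme_reference(series, shifted_only=True) == pytest.approx(
            2.0, rel=1e-6
        )

    def test_less_biased_than_dual_echo_for_long_t2star(self):
        """At long T2* the short-spacing dual-echo estimate is noise-dominated;
        the densely sampled reference fit is the less biased of the two."""
        rng = np.random.default_rng(7)
        sigma = u.noise_sigma_for_snr(50)
        t2s, nvox = 20.0, 400
        p2_amp = 100.0 * u.spgr_saturation(1000.0, 9.24, 11.0)
        ets_amp = 100.0 * u.spgr_saturation(1000.0, 13.0, 12.0)
        tes = etsme_echo_times()
        dual, ref = [], []
        for _ in range(200):
            # voxelwise dual echo over a VOI, then the VOI mean
            m2 = _rician(np.full(nvox, p2_amp * np.exp(-0.03 / t2s)), sigma, rng)
            m3 = _rician(np.full(nvox, p2_amp * np.exp(-2.46 / t2s)), sigma, rng)
            ok = m2 > m3
            est = np.clip((2.46 - 0.03) / np.log(m2[ok] / m3[ok]), None, 100.0)
            dual.append(est.mean())
            voi_mean = _rician(
                np.tile(ets_amp * np.exp(-tes / t2s), (nvox, 1)), sigma, rng
            ).mean(axis=0)
            ref.append(u.etsme_reference(EchoSeries(tes, voi_mean)))
        assert abs(np.mean(ref) - t2s) < abs(np.mean(dual) - t2s)


class TestNoiseFloorBias:
    def test_late_echo_overestimates_short_t2star(self):
        """With the later echo at 4.92 ms a T2* = 2 ms signal decays into the
        Rician floor, inflating the estimate; at 2.46 ms it does not."""
        rng = np.random.default_rng(42)
        sigma = u.noise_sigma_for_snr(50)
        amp = 100.0 * u.spgr_saturation(1000.0, 9.24, 11.0)
        n = 20000
        m2 = _rician(np.full(n, amp * np.exp(-0.03 / 2.0)), sigma, rng)
        bias = {}
        for te3 in (2.46, 4.92):
            m3 = _rician(np.full(n, amp * np.exp(-te3 / 2.0)), sigma, rng)
            ok = m2 > m3
            est = np.clip((te3 - 0.03) / np.log(m2[ok] / m3[ok]), None, 100.0)
            bias[te3] = (est.mean() - 2.0) / 2.0
        assert bias[4.92] > 0.05
        assert bias[4.92] > 2 * abs(bias[2.46])
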