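import numpy as np
import pytest

from duonuc import b1map, ptx
from duonuc.b1map import (
    afi_steady_state_signals,
    b1_minus_map,
    b1_plus_efficiency,
    fa_map_afi,
    fa_map_double_angle,
    normalize_fa,
    relative_channel_maps,
    simulate_fa_map,
)
from duonuc.geometry import GridGeometry
from duonuc.phantom import ChannelFieldSet, make_array_fields
from duonuc.recon import ImageVolume


def _vol(geom, data):
    return ImageVolume(geom, np.asarray(data, dtype=float), "na")


@pytest.fixture(scope="module")
def geom():
    return GridGeometry.isotropic(8, 10.0)


class TestDoubleAngle:
    def test_zero_double_angle_signal_gives_90_degrees(self, geom):
        fa = fa_map_double_angle(_vol(geom, np.ones(geom.shape)),
                                 _vol(geom, np.zeros(geom.shape)))
        assert np.all(fa.fa[fa.valid] == pytest.approx(90.0))

    def test_sixty_degree_closed_form(self, geom):
        s1 = np.full(geom.shape, np.sin(np.deg2rad(60.0)))
        s2 = np.full(geom.shape, np.sin(np.deg2rad(120.0)))
        fa = fa_map_double_angle(_vol(geom, s1), _vol(geom, s2))
        np.testing.assert_allclose(fa.fa[fa.valid], 60.0, atol=1e-12)

    def test_round_trip_over_flip_angle_range(self, geom):
        """sin-model forward simulation inverts exactly for 10..85 deg."""
        for alpha in np.arange(10.0, 86.0, 5.0):
            s1 = np.full(geom.shape, np.sin(np.deg2rad(alpha)))
            s2 = np.full(geom.shape, np.sin(np.deg2rad(2 * alpha)))
            fa = fa_map_double_angle(_vol(geom, np.abs(s1)), _vol(geom, np.abs(s2)))
            np.testing.assert_allclose(fa.fa[fa.valid], alpha, atol=1e-9)

    def test_zero_signal_voxels_masked(self, geom):
        s1 = np.ones(geom.shape)
        s1[0, 0, 0] = 0.0
        fa = fa_map_double_angle(_vol(geom, s1), _vol(geom, np.ones(geom.shape)))
        assert not fa.valid[0, 0, 0]


class TestAfi:
    def test_ratio_times_n_equals_one_gives_90(self, geom):
        n = 5.0
        s_long = np.ones(geom.shape)
        s_short = np.full(geom.shape, 1.0 / n)  # r*n = 1
        fa = fa_map_afi(_vol(geom, s_long), _vol(geom, s_short), 75.0, 15.0)
        np.testing.assert_allclose(fa.fa[fa.valid], 90.0, atol=1e-12)

    def test_equal_signals_give_zero(self, geom):
        s = np.ones(geom.shape)
        fa = fa_map_afi(_vol(geom, s), _vol(geom, s), 75.0, 15.0)
        np.testing.assert_allclose(fa.fa[fa.valid], 0.0, atol=1e-12)

    def test_bloch_steady_state_round_trip(self, geom):
        """Two-TR Bloch steady-state oracle: AFI inversion recovers the true
        flip angle to < 0.5 deg (T1 = 1000 ms, TR 75/15 ms)."""
        for true_fa in np.arange(10.0, 86.0, 5.0):
            s_long, s_short = afi_steady_state_signals(true_fa, 75.0, 15.0, 1000.0)
            fa = fa_map_afi(
                _vol(geom, np.full(geom.shape, s_long)),
                _vol(geom, np.full(geom.shape, s_short)),
                75.0, 15.0,
            )
            assert np.all(np.abs(fa.fa[fa.valid] - true_fa) < 0.5)

    def test_invalid_tr_order_raises(self, geom):
        v = _vol(geom, np.ones(geom.shape))
        with pytest.raises(ValueError):
            fa_map_afi(v, v, 15.0, 75.0)


class TestFaErrorScalesWithNoise:
    def test_da_and_afi_noise_scaling(self):
        """FA error grows ~linearly with the signal noise sigma."""
        geom = GridGeometry.isotropic(12, 8.0)
        rng = np.random.default_rng(0)
        true_fa = 60.0
        errs = {}
        for sig in (0.001, 0.002):
            s1 = np.abs(np.sin(np.deg2rad(true_fa)) + rng.normal(0, sig, geom.shape))
            s2 = np.abs(np.sin(np.deg2rad(2 * true_fa)) + rng.normal(0, sig, geom.shape))
            fa = fa_map_double_angle(_vol(geom, s1), _vol(geom, s2))
            errs[sig] = np.sqrt(np.mean((fa.fa[fa.valid] - true_fa) ** 2))
        assert errs[0.002] / errs[0.001] == pytest.approx(2.0, rel=0.35)


class TestB1Minus:
    def test_sine_signal_gives_unit_map(self, geom):
        fa_deg = np.full(geom.shape, 47.0)
        fa = b1map.FAMap(geom, fa_deg, 47.0, np.ones(geom.shape, bool))
        sig = _vol(geom, np.sin(np.deg2rad(fa_deg)))
        out = b1_minus_map(sig, fa)
        np.testing.assert_allclose(out.data, 1.0, atol=1e-12)

    def test_scale_invariance_through_normalization(self, geom):
        rng = np.random.default_rng(1)
        fa_deg = rng.uniform(30, 80, geom.shape)
        fa = b1map.FAMap(geom, fa_deg, 60.0, np.ones(geom.shape, bool))
        s = rng.uniform(0.5, 1.0, geom.shape)
        a = b1_minus_map(_vol(geom, s), fa)
        b = b1_minus_map(_vol(geom, 2.0 * s), fa)
        np.testing.assert_allclose(a.data, b.data, rtol=1e-12)

    def test_recovers_smooth_receive_profile(self):
        """Forward-simulated signal S = B1rx * sin(FA) inverts to the
        receive profile within 1% RMS."""
        geom = GridGeometry.isotropic(16, 8.0)
        xx, yy, _ = geom.meshgrid()
        profile = 1.0 + 0.3 * xx / geom.fov[0] + 0.2 * (yy / geom.fov[1]) ** 2
        rng = np.random.default_rng(2)
        fa_deg = rng.uniform(20, 80, geom.shape)
        fa = b1map.FAMap(geom, fa_deg, 60.0, np.ones(geom.shape, bool))
        sig = _vol(geom, profile * np.sin(np.deg2rad(fa_deg)))
        out = b1_minus_map(sig, fa)
        ref = profile / profile.mean()
        assert np.sqrt(np.mean((out.data - ref) ** 2)) / np.mean(ref) < 0.01

    def test_low_flip_voxels_masked(self, geom):
        fa_deg = np.full(geom.shape, 50.0)
        fa_deg[0, 0, 0] = 2.0  # below the 5 deg validity floor
        fa = b1map.FAMap(geom, fa_deg, 50.0, np.ones(geom.shape, bool))
        out = b1_minus_map(_vol(geom, np.ones(geom.shape)), fa)
        assert np.isnan(out.data[0, 0, 0])


class TestB1PlusEfficiency:
    def test_zero_fa_gives_zero(self, geom):
        fa = b1map.FAMap(geom, np.zeros(geom.shape), 0.0, np.ones(geom.shape, bool))
        eff = b1_plus_efficiency(fa, 2.0, 100.0, 11.262)
        assert np.all(eff.eta_nt_per_v == 0)

    def test_sodium_example_value(self, geom):
        # FA 82 deg, 2 ms pulse, 100 V applied, sodium gamma:
        # eta = (82 deg in rad) / (2 pi * 11.262e6 * 0.002 * 100) ~ 101.1 nT/V
        fa = b1map.FAMap(geom, np.full(geom.shape, 82.0), 82.0, np.ones(geom.shape, bool))
        eff = b1_plus_efficiency(fa, 2.0, 100.0, 11.262)
        expected = np.deg2rad(82.0) / (2 * np.pi * 11.262e6 * 0.002 * 100.0) * 1e9
        assert expected == pytest.approx(101.1, abs=0.1)
        np.testing.assert_allclose(eff.eta_nt_per_v, expected, rtol=1e-12)

    def test_doubling_voltage_halves_efficiency(self, geom):
        fa = b1map.FAMap(geom, np.full(geom.shape, 45.0), 45.0, np.ones(geom.shape, bool))
        a = b1_plus_efficiency(fa, 2.0, 100.0, 42.577)
        b = b1_plus_efficiency(fa, 2.0, 200.0, 42.577)
        np.testing.assert_allclose(a.eta_nt_per_v, 2.0 * b.eta_nt_per_v, rtol=1e-12)


class TestRelativeChannelMaps:
    def test_identical_channels_quarter_share(self, geom):
        imgs = [ImageVolume(geom, np.ones(geom.shape, complex), "h") for _ in range(4)]
        maps, valid = relative_channel_maps(imgs)
        np.testing.assert_allclose(np.abs(maps[:, valid]), 0.25, atol=1e-12)

    def test_magnitudes_sum_to_one(self, geom):
        rng = np.random.default_rng(3)
        imgs = [
            ImageVolume(geom, rng.standard_normal(geom.shape)
                        + 1j * rng.standard_normal(geom.shape), "h")
            for _ in range(5)
        ]
        maps, valid = relative_channel_maps(imgs)
        np.testing.assert_allclose(np.sum(np.abs(maps), axis=0)[valid], 1.0, atol=1e-12)

    def test_ground_truth_up_to_voxelwise_scale(self):
        """Relative maps preserve inter-channel ratios of the true fields."""
        geom = GridGeometry.isotropic(8, 12.0)
        fields = make_array_fields(geom, n_ch=4, seed=5)
        imgs = [ImageVolume(geom, fields.tx_fields[c], "h") for c in range(4)]
        maps, valid = relative_channel_maps(imgs)
        ratio_maps = maps[1][valid] / maps[0][valid]
        ratio_truth = fields.tx_fields[1][valid] / fields.tx_fields[0][valid]
        np.testing.assert_allclose(ratio_maps, ratio_truth, rtol=1e-9)


class TestSimulateFaMap:
    def test_single_channel_proportional_to_field(self, geom):
        fields = ChannelFieldSet(
            geom, np.abs(np.random.default_rng(6).standard_normal((1,) + geom.shape))
            .astype(complex), np.ones((1,) + geom.shape, complex), "h",
        )
        shim = ptx.ShimSolution(np.ones(1, dtype=complex), 0.0)
        fa = simulate_fa_map(fields, shim, reference_voltage=1.0)
        mag = np.abs(fields.tx_fields[0])
        np.testing.assert_allclose(
            fa.fa / fa.fa.max(), mag / mag.max(), rtol=1e-9
        )

    def test_constructive_two_channel_doubles(self, geom):
        one = np.ones((1,) + geom.shape, complex)
        f1 = ChannelFieldSet(geom, one, one, "h")
        f2 = ChannelFieldSet(geom, np.repeat(one, 2, axis=0), one, "h")
        fa1 = simulate_fa_map(f1, ptx.ShimSolution(np.ones(1, complex), 0.0), 1.0)
        fa2 = simulate_fa_map(f2, ptx.ShimSolution(np.ones(2, complex), 0.0), 1.0)
        np.testing.assert_allclose(fa2.fa, 2.0 * fa1.fa, rtol=1e-12)

    def test_kt_with_single_zero_blip_subpulse_equals_shim(self, geom):
        fields = make_array_fields(geom, n_ch=4, seed=7)
        w = np.exp(1j * np.array([0.0, 0.5, 1.0, 1.5]))
        shim = ptx.ShimSolution(w, 0.0, t_pulse_ms=2.0)
        kt = ptx.KTPulse(w[None, :], np.zeros((1, 3)), np.array([2.0]), 0.0)
        fa_shim = simulate_fa_map(fields, shim, 10.0)
        fa_kt = simulate_fa_map(fields, kt, 10.0)
        np.testing.assert_allclose(fa_kt.fa, fa_shim.fa, rtol=1e-12)


class TestNormalizeFa:
    def test_constant_map_becomes_ones(self, geom):
        fa = b1map.FAMap(geom, np.full(geom.shape, 33.0), 33.0, np.ones(geom.shape, bool))
        roi = np.ones(geom.shape, bool)
        out = normalize_fa(fa, roi)
        np.testing.assert_allclose(out.fa, 1.0, atol=1e-12)

    def test_roi_mean_is_one_and_cv_unchanged(self, geom):
        rng = np.random.default_rng(8)
        fa_deg = rng.uniform(10, 80, geom.shape)
        fa = b1map.FAMap(geom, fa_deg, 45.0, np.ones(geom.shape, bool))
        roi = np.zeros(geom.shape, bool)
        roi[2:6, 2:6, 2:6] = True
        out = normalize_fa(fa, roi)
        assert np.mean(out.fa[roi]) == pytest.approx(1.0, abs=1e-12)
        cv_before = np.std(fa.fa[roi]) / np.mean(fa.fa[roi])
        cv_after = np.std(out.fa[roi]) / np.mean(out.fa[roi])
        assert cv_after == pytest.approx(cv_before, rel=1e-12)

    def test_empty_roi_raises(self, geom):
        fa = b1map.FAMap(geom, np.full(geom.shape, 33.0), 33.0, np.ones(geom.shape, bool))
        with pytest.raises(ValueError):
            normalize_fa(fa, np.zeros(geom.shape, bool))


class TestEfficiencySimulationConsistency:
    def test_efficiency_from_simulated_fa_recovers_field(self, geom):
        """Closing the loop: simulate FA from a single-channel map, convert
        back to efficiency, and recover the field magnitude to 1e-6."""
        rng = np.random.default_rng(9)
        mag = np.abs(rng.standard_normal(geom.shape)) + 0.1
        fields = ChannelFieldSet(
            geom, mag[None].astype(complex), np.ones((1,) + geom.shape, complex), "h"
        )
        shim = ptx.ShimSolution(np.ones(1, complex), 0.0, t_pulse_ms=2.0)
        u = 5.0
        fa = simulate_fa_map(fields, shim, reference_voltage=u)
        eff = b1_plus_efficiency(fa, shim.t_pulse_ms, u, 42.577)
        np.testing.assert_allclose(eff.eta_nt_per_v, mag, rtol=1e-6)
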