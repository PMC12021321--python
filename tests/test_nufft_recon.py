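import numpy as np
import pytest

from duonuc import nufft, recon, sequence, trajectory
from duonuc.geometry import GridGeometry
from duonuc.phantom import CompartmentSpec, make_torso_phantom
from duonuc.recon import (
    ImageVolume,
    combine_channels,
    reconstruct,
    relative_difference_map,
    resample_to,
)
from duonuc.sequence import AcquiredData

from conftest import dft_oracle_adjoint, dft_oracle_forward


class TestNufftAgainstDftOracle:
    def test_adjoint_matches_brute_force_dft(self, geom16, small_traj):
        rng = np.random.default_rng(3)
        n = small_traj.n_proj * small_traj.n_samples
        data = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        coords = small_traj.flat_coords()
        w = small_traj.flat_dcf()
        ours = nufft.adjoint(data, geom16, coords, w)
        # oracle on a subsample for speed, compared on the same subsample
        oracle = dft_oracle_adjoint(data[:2000], geom16, coords[:2000], w[:2000])
        ours_sub = nufft.adjoint(data[:2000], geom16, coords[:2000], w[:2000])
        rel = np.linalg.norm(ours_sub - oracle) / np.linalg.norm(oracle)
        assert rel < 1e-6
        assert ours.shape == geom16.shape

    def test_forward_matches_brute_force_dft(self, geom16):
        rng = np.random.default_rng(4)
        img = rng.standard_normal(geom16.shape)
        coords = rng.uniform(-0.125, 0.125, (150, 3))
        oracle = dft_oracle_forward(img, geom16, coords)
        ours = nufft.forward(img, geom16, coords)
        assert np.linalg.norm(ours - oracle) / np.linalg.norm(oracle) < 1e-6

    def test_gridding_path_matches_oracle(self, geom16):
        rng = np.random.default_rng(5)
        img = rng.standard_normal(geom16.shape) + 1j * rng.standard_normal(geom16.shape)
        coords = rng.uniform(-0.125, 0.125, (400, 3))
        op = nufft.GriddingNufft(geom16, coords)
        fwd_oracle = dft_oracle_forward(img, geom16, coords)
        assert (
            np.linalg.norm(op.forward(img) - fwd_oracle) / np.linalg.norm(fwd_oracle)
            < 1e-3
        )
        data = rng.standard_normal(400) + 1j * rng.standard_normal(400)
        adj_oracle = dft_oracle_adjoint(data, geom16, coords)
        assert (
            np.linalg.norm(op.adjoint(data) - adj_oracle) / np.linalg.norm(adj_oracle)
            < 1e-3
        )

    def test_gridding_is_exact_adjoint_pair(self, geom16):
        """<F x, y> == <x, F^H y> to machine precision for the gridding op."""
        rng = np.random.default_rng(6)
        coords = rng.uniform(-0.125, 0.125, (300, 3))
        op = nufft.GriddingNufft(geom16, coords)
        img = rng.standard_normal(geom16.shape) + 1j * rng.standard_normal(geom16.shape)
        data = rng.standard_normal(300) + 1j * rng.standard_normal(300)
        lhs = np.vdot(data, op.forward(img))
        rhs = np.vdot(op.adjoint(data), img)
        assert abs(lhs - rhs) / abs(lhs) < 1e-12

    def test_forward_of_center_delta_is_flat(self, geom16):
        img = np.zeros(geom16.shape)
        center = tuple(s // 2 for s in geom16.shape)
        img[center] = 1.0
        rng = np.random.default_rng(7)
        coords = rng.uniform(-0.125, 0.125, (100, 3))
        s = nufft.forward(img, geom16, coords)
        np.testing.assert_allclose(np.abs(s), 1.0, atol=1e-9)


class TestReconstruct:
    def test_delta_phantom_peaks_at_center(self, geom16, small_traj):
        img = np.zeros(geom16.shape)
        center = tuple(s // 2 for s in geom16.shape)
        img[center] = 1.0
        samples = nufft.forward(img, geom16, small_traj.flat_coords())
        acq = AcquiredData(
            samples.reshape(small_traj.n_proj, small_traj.n_samples, 1), "na", 0.0, None
        )
        out = combine_channels(reconstruct(acq, small_traj))
        assert np.unravel_index(np.argmax(out.data), out.data.shape) == center

    def test_shape_mismatch_raises(self, geom16, small_traj):
        acq = AcquiredData(np.zeros((3, 5, 1), dtype=complex), "na", 0.0, None)
        with pytest.raises(ValueError, match="match"):
            reconstruct(acq, small_traj)

    def test_hamming_reduces_first_psf_sidelobe(self, geom16):
        """Radial PSF: first sidelobe magnitude strictly smaller with filter."""
        dirs = trajectory.golden_angle_directions(1500, "half")
        ro = trajectory.da_radial_readout(0.125, 80, 5.0)
        traj = trajectory.build_trajectory(dirs, ro, geom16)
        n = traj.n_proj * traj.n_samples
        acq = AcquiredData(np.ones((traj.n_proj, traj.n_samples, 1), dtype=complex),
                           "na", 0.0, None)
        psf_h = np.abs(combine_channels(reconstruct(acq, traj, hamming=True)).data)
        psf_n = np.abs(combine_channels(reconstruct(acq, traj, hamming=False)).data)
        c = geom16.shape[0] // 2
        line_h = psf_h[c:, c, c] / psf_h[c, c, c]
        line_n = psf_n[c:, c, c] / psf_n[c, c, c]

        def first_sidelobe(line):
            i = 1
            while i + 1 < len(line) and line[i + 1] < line[i]:
                i += 1  # descend the main lobe
            return max(line[i:])

        assert first_sidelobe(line_h) < first_sidelobe(line_n)


class TestCombineChannels:
    def test_single_channel_magnitude_unchanged(self, geom16):
        rng = np.random.default_rng(0)
        img = ImageVolume(geom16, rng.standard_normal(geom16.shape)
                          + 1j * rng.standard_normal(geom16.shape), "na")
        out = combine_channels([img])
        np.testing.assert_allclose(out.data, np.abs(img.data), atol=1e-12)

    def test_two_identical_channels_scale_sqrt2(self, geom16):
        rng = np.random.default_rng(1)
        img = ImageVolume(geom16, rng.standard_normal(geom16.shape) + 0j, "na")
        out = combine_channels([img, img])
        np.testing.assert_allclose(out.data, np.sqrt(2) * np.abs(img.data), rtol=1e-12)

    def test_rss_dominates_each_channel(self, geom16):
        rng = np.random.default_rng(2)
        imgs = [
            ImageVolume(geom16, rng.standard_normal(geom16.shape)
                        + 1j * rng.standard_normal(geom16.shape), "na")
            for _ in range(4)
        ]
        out = combine_channels(imgs)
        for im in imgs:
            assert np.all(out.data >= np.abs(im.data) - 1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            combine_channels([])


class TestResample:
    def test_identity(self, geom16):
        rng = np.random.default_rng(3)
        img = ImageVolume(geom16, rng.standard_normal(geom16.shape), "na")
        out = resample_to(img, geom16)
        np.testing.assert_allclose(out.data, img.data, atol=1e-12)

    def test_6mm_to_2mm_triples_dimensions(self):
        src = GridGeometry.isotropic(8, 6.0)
        img = ImageVolume(src, np.ones(src.shape), "na")
        target = GridGeometry.isotropic(24, 2.0)
        out = resample_to(img, target)
        assert out.data.shape == (24, 24, 24)

    def test_exact_on_linear_ramp_interior(self):
        src = GridGeometry.isotropic(16, 4.0)
        xx, _, _ = src.meshgrid()
        img = ImageVolume(src, 2.0 * xx + 5.0, "na")
        target = GridGeometry.isotropic(24, 2.0)
        out = resample_to(img, target)
        tx, _, _ = target.meshgrid()
        interior = np.abs(tx) < 0.5 * src.fov[0] - 2 * src.voxel_size[0]
        np.testing.assert_allclose(out.data[interior], (2.0 * tx + 5.0)[interior], rtol=1e-12)


class TestRelativeDifferenceMap:
    def test_identical_images_zero(self, geom16):
        rng = np.random.default_rng(4)
        img = ImageVolume(geom16, 1.0 + rng.random(geom16.shape), "na")
        _, mean, _ = relative_difference_map(img, img, np.ones(geom16.shape, bool))
        assert mean == 0.0

    def test_forced_scale_gives_printed_mean(self, geom16):
        """x = 0.811 y gives a -18.9% mean relative difference by construction."""
        rng = np.random.default_rng(5)
        y = ImageVolume(geom16, 1.0 + rng.random(geom16.shape), "na")
        x = ImageVolume(geom16, 0.811 * y.data, "na")
        _, mean, _ = relative_difference_map(x, y, np.ones(geom16.shape, bool))
        assert mean == pytest.approx(-0.189, abs=1e-12)

    def test_empty_mask_raises(self, geom16):
        img = ImageVolume(geom16, np.ones(geom16.shape), "na")
        with pytest.raises(ValueError, match="empty"):
            relative_difference_map(img, img, np.zeros(geom16.shape, bool))

    def test_zero_denominator_voxels_excluded_and_counted(self, geom16):
        y = np.ones(geom16.shape)
        y[0, 0, 0] = 0.0
        x = ImageVolume(geom16, np.ones(geom16.shape), "na")
        _, mean, n_excl = relative_difference_map(
            x, ImageVolume(geom16, y, "na"), np.ones(geom16.shape, bool)
        )
        assert n_excl == 1 and mean == 0.0


class TestParameterRecovery:
    def test_concentration_ratio_recovered(self):
        """simulate -> reconstruct on a two-compartment phantom recovers the
        blood/myocardium concentration ratio within 5% (no noise, uniform
        fields, matched relaxation so signal is proportional to m0)."""
        geom = GridGeometry.isotropic(32, 4.0)
        comps = [
            CompartmentSpec("myocardium", (0.0, 0.0, 0.0), (48.0, 48.0, 48.0),
                            43.0, 35.0, 20.0),
            CompartmentSpec("blood", (0.0, 0.0, 0.0), (26.0, 26.0, 26.0),
                            140.0, 35.0, 20.0),
        ]
        ph = make_torso_phantom(geom, comps, "na")
        kmax = trajectory.kmax_for_resolution(4.0)
        dirs = trajectory.golden_angle_directions(2000, "half")
        # wide uniform inner region: fine low-k sampling keeps the broad
        # compartments' mean levels quadrature-accurate
        ro = trajectory.da_radial_readout(kmax, 256, 5.0, k0_fraction=0.4)
        traj = trajectory.build_trajectory(dirs, ro, geom)
        from duonuc.phantom import ChannelFieldSet

        uniform = ChannelFieldSet(
            geom,
            np.ones((1,) + geom.shape, complex),
            np.ones((1,) + geom.shape, complex),
            "na",
        )
        params = sequence.SequenceParams("na", 82.0, 60.0, 1.15, 2.0, 5.0, traj.n_proj)
        acq = sequence.simulate_acquisition(ph, uniform, traj, params)
        img = combine_channels(reconstruct(acq, traj))
        xx, yy, zz = geom.meshgrid()
        r2_blood = (xx / 26) ** 2 + (yy / 26) ** 2 + (zz / 26) ** 2
        erode = 2 * 4.0  # two voxels
        inner_blood = r2_blood <= ((26 - erode) / 26) ** 2
        r2_myo = (xx / 48) ** 2 + (yy / 48) ** 2 + (zz / 48) ** 2
        inner_myo = (r2_myo <= ((48 - erode) / 48) ** 2) & (
            r2_blood >= ((26 + erode) / 26) ** 2
        )
        ratio = np.mean(img.data[inner_blood]) / np.mean(img.data[inner_myo])
        assert ratio == pytest.approx(140.0 / 43.0, rel=0.05)
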