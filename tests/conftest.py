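import numpy as np
import pytest

from duonuc import metrics, phantom, trajectory
from duonuc.geometry import GridGeometry


@pytest.fixture(scope="session")
def geom16():
    return GridGeometry.isotropic(16, 4.0)


@pytest.fixture(scope="session")
def geom24():
    return GridGeometry.isotropic(24, 6.0)


@pytest.fixture(scope="session")
def heart_roi(geom24):
    fov = geom24.fov
    return metrics.ellipsoid_roi(
        geom24,
        (0.08 * fov[0], -0.05 * fov[1], 0.0),
        tuple(0.16 * f for f in fov),
        "heart",
    ).mask


@pytest.fixture(scope="session")
def h_fields(geom24):
    return phantom.make_array_fields(geom24, n_ch=8, seed=0)


@pytest.fixture(scope="session")
def small_traj(geom16):
    """Half-projection trajectory on the 16^3 grid (exact-NUFFT sized)."""
    dirs = trajectory.golden_angle_directions(300, "half")
    ro = trajectory.da_radial_readout(
        trajectory.kmax_for_resolution(geom16.voxel_size[0]), 32, 5.0
    )
    return trajectory.build_trajectory(dirs, ro, geom16)


def dft_oracle_adjoint(samples, geometry, coords, weights=None):
    """Brute-force DFT summation oracle, written independently of the package
    transform: loops over samples, accumulating each plane wave on the grid."""
    xx, yy, zz = geometry.meshgrid()
    out = np.zeros(geometry.shape, dtype=complex)
    data = samples if weights is None else samples * weights
    for s, k in zip(data, coords):
        out += s * np.exp(2j * np.pi * (k[0] * xx + k[1] * yy + k[2] * zz))
    return out


def dft_oracle_forward(image, geometry, coords):
    xx, yy, zz = geometry.meshgrid()
    out = np.empty(coords.shape[0], dtype=complex)
    for i, k in enumerate(coords):
        out[i] = np.sum(image * np.exp(-2j * np.pi * (k[0] * xx + k[1] * yy + k[2] * zz)))
    return out
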