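"""Density-adapted 3D radial trajectories with golden-means projection ordering.

The readout is specified directly as k(t): uniform k-space speed out to a
radius ``k0 = k0_fraction * kmax``, then a density-adapted segment where the
sampling density compensates the 1/k^2 dilution of radial sampling, i.e.
``k^2 * dk/dt = const`` so that ``k(t) = (k0^3 + 3 k0^2 g (t - t0))^(1/3)``
with ``g`` the k-space speed of the uniform segment. Gradient hardware limits
(slew, amplitude) are deliberately not modeled.

Projection directions follow the 2D-golden-means construction
(lambda1 = 0.4656, lambda2 = 0.6823): for projection n,
``z_n = 2 frac(n lambda1) - 1`` (half projections, full sphere) or
``z_n = frac(n lambda1)`` (full projections, hemisphere; the antipodal ray is
covered by the negative-k half of the readout), and
``phi_n = 2 pi frac(n lambda2)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .geometry import GridGeometry

# 2D golden means: lambda1 = 1/psi^2, lambda2 = 1/psi with psi the
# supergolden ratio (real root of x^3 = x^2 + 1). Conventionally quoted
# truncated as 0.4656 and 0.6823; full precision is required to avoid
# exact duplicate directions for large n.
_PSI = 1.4655712318767682
GOLDEN_MEAN_1 = 1.0 / _PSI**2  # 0.46557123...
GOLDEN_MEAN_2 = 1.0 / _PSI  # 0.68232780...

Scheme = Literal["half", "full"]


@dataclass(frozen=True)
class ProjectionDirections:
    """Unit projection directions on the sphere."""

    unit_vectors: np.ndarray  # (n, 3)
    scheme: Scheme
    lambda1: float
    lambda2: float

    @property
    def n(self) -> int:
        return self.unit_vectors.shape[0]


@dataclass(frozen=True)
class RadialReadout:
    """Radial k-space sample positions along one projection.

    ``k_mags`` are non-negative magnitudes for half (center-out) projections
    and signed values spanning -kmax..+kmax for full (center-through)
    projections. ``t_samples`` are sample times in ms from readout start.
    """

    k_mags: np.ndarray  # (n_samples,), 1/mm
    t_samples: np.ndarray  # (n_samples,), ms
    kmax: float
    k0_fraction: float
    mode: Scheme

    @property
    def n_samples(self) -> int:
        return self.k_mags.shape[0]


@dataclass(frozen=True)
class TrajectorySet:
    """Full set of k-space sample coordinates plus density compensation."""

    coords: np.ndarray  # (n_proj, n_samples, 3), 1/mm
    dcf: np.ndarray  # (n_proj, n_samples), >= 0
    geometry: GridGeometry
    readout: RadialReadout | None = None

    @property
    def n_proj(self) -> int:
        return self.coords.shape[0]

    @property
    def n_samples(self) -> int:
        return self.coords.shape[1]

    def flat_coords(self) -> np.ndarray:
        return self.coords.reshape(-1, 3)

    def flat_dcf(self) -> np.ndarray:
        return self.dcf.reshape(-1)


def golden_angle_directions(
    n: int,
    scheme: Scheme = "half",
    lambda1: float = GOLDEN_MEAN_1,
    lambda2: float = GOLDEN_MEAN_2,
) -> ProjectionDirections:
    """Generate ``n`` golden-means projection directions.

    Half projections cover the full sphere (z in [-1, 1]); full projections
    only need a hemisphere (z in [0, 1)) because the readout itself passes
    through the k-space center and covers the antipode.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if scheme not in ("half", "full"):
        raise ValueError(f"scheme must be 'half' or 'full', got {scheme!r}")
    idx = np.arange(1, n + 1, dtype=np.float64)
    frac1 = np.mod(idx * lambda1, 1.0)
    frac2 = np.mod(idx * lambda2, 1.0)
    if scheme == "half":
        z = 2.0 * frac1 - 1.0
    else:
        z = frac1
    phi = 2.0 * np.pi * frac2
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    vecs = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    return ProjectionDirections(vecs, scheme, lambda1, lambda2)


def _half_profile(kmax: float, n_samples: int, t_ro: float, k0_fraction: float):
    """k(t) and t for a center-out readout with density adaptation."""
    k0 = k0_fraction * kmax
    # speed g of the uniform segment follows from reaching kmax at t_ro:
    # kmax^3 = k0^3 + 3 k0^2 g (t_ro - k0/g)  =>  g = (kmax^3 + 2 k0^3) / (3 k0^2 t_ro)
    g = (kmax**3 + 2.0 * k0**3) / (3.0 * k0**2 * t_ro)
    t0 = k0 / g
    t = np.linspace(0.0, t_ro, n_samples)
    k = np.where(
        t <= t0,
        g * t,
        np.cbrt(k0**3 + 3.0 * k0**2 * g * np.clip(t - t0, 0.0, None)),
    )
    k[-1] = kmax  # exact endpoint
    return k, t


def da_radial_readout(
    kmax: float,
    n_samples: int,
    t_ro: float,
    k0_fraction: float = 0.2,
    mode: Scheme = "half",
) -> RadialReadout:
    """Build a density-adapted radial readout.

    Parameters
    ----------
    kmax
        Maximum sampled spatial frequency, 1/mm (Nyquist: 1/(2*resolution)).
    n_samples
        Samples per projection (must be odd for ``mode='full'`` so the
        k-space center is sampled exactly once).
    t_ro
        Readout duration in ms; samples are uniformly spaced in time.
    k0_fraction
        Fraction of kmax out to which sampling is uniform in k.
    """
    if not 0.0 < k0_fraction < 1.0:
        raise ValueError(f"k0_fraction must be in (0, 1), got {k0_fraction}")
    if n_samples < 2:
        raise ValueError(f"n_samples must be >= 2, got {n_samples}")
    if kmax <= 0 or t_ro <= 0:
        raise ValueError("kmax and t_ro must be positive")
    if mode == "half":
        k, t = _half_profile(kmax, n_samples, t_ro, k0_fraction)
    elif mode == "full":
        if n_samples % 2 == 0:
            raise ValueError("full mode requires odd n_samples (one center sample)")
        m = n_samples // 2 + 1
        kh, th = _half_profile(kmax, m, t_ro / 2.0, k0_fraction)
        k = np.concatenate([-kh[:0:-1], kh])
        t = np.concatenate([t_ro / 2.0 - th[:0:-1], t_ro / 2.0 + th])
    else:
        raise ValueError(f"mode must be 'half' or 'full', got {mode!r}")
    return RadialReadout(k, t, float(kmax), float(k0_fraction), mode)


def kmax_for_resolution(resolution_mm: float) -> float:
    """Nyquist kmax (1/mm) for a nominal isotropic resolution in mm."""
    return 1.0 / (2.0 * resolution_mm)


def _half_dcf(k: np.ndarray, kmax: float) -> np.ndarray:
    """Per-sample spherical-shell volume fractions for one center-out ray.

    Sample i owns the shell between the |k| midpoints to its neighbors;
    weights are the shell volumes (4/3) pi (k_hi^3 - k_lo^3) divided by the
    full solid angle, i.e. (k_hi^3 - k_lo^3)/3 per unit solid angle. At k=0
    the inner edge is 0, so the center weight is finite and positive.
    """
    edges = np.empty(k.size + 1)
    edges[1:-1] = 0.5 * (k[:-1] + k[1:])
    edges[0] = k[0]  # = 0 for center-out
    edges[-1] = kmax
    return (edges[1:] ** 3 - edges[:-1] ** 3) / 3.0


def build_trajectory(
    dirs: ProjectionDirections,
    readout: RadialReadout,
    geometry: GridGeometry,
) -> TrajectorySet:
    """Combine directions and readout into sample coordinates with analytic
    density-compensation weights.

    DCF is the k-space volume owned by each sample: radial shell volumes
    split over the rays that sample them, normalized so the total equals the
    volume of the kmax ball. Used as quadrature weights, the adjoint NUFFT
    then approximates the inverse Fourier transform.
    """
    if dirs.scheme != readout.mode:
        raise ValueError(
            f"direction scheme {dirs.scheme!r} does not match readout mode {readout.mode!r}"
        )
    coords = dirs.unit_vectors[:, None, :] * readout.k_mags[None, :, None]
    if readout.mode == "half":
        # n rays cover the sphere of directions
        per_ray = _half_dcf(readout.k_mags, readout.kmax)
        dcf_1d = 4.0 * np.pi * per_ray / dirs.n
    else:
        # each full projection is two rays; 2n rays cover the sphere
        c = readout.n_samples // 2
        pos = _half_dcf(readout.k_mags[c:], readout.kmax)
        neg = _half_dcf(-readout.k_mags[c::-1], readout.kmax)[::-1]
        dcf_1d = np.concatenate([neg[:-1], pos])
        # the single center sample covers the k=0 cell of both half-rays
        dcf_1d[c] = 2.0 * pos[0]
        dcf_1d = 4.0 * np.pi * dcf_1d / (2.0 * dirs.n)
    dcf = np.broadcast_to(dcf_1d, (dirs.n, readout.n_samples)).copy()
    return TrajectorySet(coords, dcf, geometry, readout)


def save_trajectory(path, traj: TrajectorySet) -> None:
    """Persist a trajectory as an NPZ container."""
    np.savez(
        path,
        coords=traj.coords,
        dcf=traj.dcf,
        shape=np.asarray(traj.geometry.shape),
        voxel_size=np.asarray(traj.geometry.voxel_size),
        origin=np.asarray(traj.geometry.origin),
    )


def load_trajectory(path) -> TrajectorySet:
    with np.load(path) as f:
        geom = GridGeometry(
            tuple(int(v) for v in f["shape"]),
            tuple(float(v) for v in f["voxel_size"]),
            tuple(float(v) for v in f["origin"]),
        )
        return TrajectorySet(f["coords"], f["dcf"], geom)
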