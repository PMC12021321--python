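"""Grid geometry shared by phantoms, field maps, trajectories and images."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridGeometry:
    """Regular 3D voxel grid in physical (mm) coordinates.

    Parameters
    ----------
    shape
        Number of voxels per axis.
    voxel_size
        Voxel edge length per axis in mm.
    origin
        Physical position (mm) of the center of voxel (0, 0, 0). The default
        places the *grid center* at the physical origin, which is also the
        k-space center convention used throughout.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        vs = tuple(float(v) for v in self.voxel_size)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)
        if self.origin is None:
            # grid center at physical 0: origin = -(N-1)/2 * dx
            origin = tuple(-(s - 1) / 2.0 * v for s, v in zip(shape, vs))
        else:
            origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "origin", origin)

    @classmethod
    def isotropic(cls, n: int, voxel_mm: float) -> "GridGeometry":
        return cls((n, n, n), (voxel_mm, voxel_mm, voxel_mm))

    @property
    def fov(self) -> tuple[float, float, float]:
        """Field of view per axis in mm."""
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size))

    @property
    def kmax(self) -> tuple[float, float, float]:
        """Nyquist k-space extent per axis, 1/(2*voxel_size), in 1/mm."""
        return tuple(1.0 / (2.0 * v) for v in self.voxel_size)

    def voxel_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical voxel-center coordinates (mm) per axis (1D arrays)."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.voxel_size[a]
            for a in range(3)
        )

    def meshgrid(self) -> tuple[np.ndarray, ...]:
        """Broadcastable 3D physical coordinate arrays (mm)."""
        x, y, z = self.voxel_coords()
        return np.meshgrid(x, y, z, indexing="ij")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridGeometry):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.origin, other.origin)
        )

    def __hash__(self) -> int:
        return hash((self.shape, self.voxel_size, self.origin))
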