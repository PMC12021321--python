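"""Image reconstruction from radial k-space data.

Samples are weighted by the analytic density-compensation function and,
optionally, by a radial Hamming window w(k) = 0.54 + 0.46 cos(pi |k|/kmax)
before the adjoint nonuniform Fourier transform grids them onto the image.
Channels are combined as root-sum-of-squares magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates

from . import nufft
from .geometry import GridGeometry
from .phantom import Nucleus
from .sequence import AcquiredData
from .trajectory import TrajectorySet


@dataclass(frozen=True)
class ImageVolume:
    geometry: GridGeometry
    data: np.ndarray  # complex or real voxel map
    nucleus: Nucleus
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.shape != self.geometry.shape:
            raise ValueError("data shape must match geometry shape")

    def magnitude(self) -> "ImageVolume":
        return ImageVolume(self.geometry, np.abs(self.data), self.nucleus, dict(self.meta))


def hamming_radial(k_mag: np.ndarray, kmax: float) -> np.ndarray:
    """Radial Hamming window on |k| <= kmax."""
    return 0.54 + 0.46 * np.cos(np.pi * np.clip(k_mag / kmax, 0.0, 1.0))


def reconstruct(
    acq: AcquiredData,
    traj: TrajectorySet,
    hamming: bool = True,
    method: str = "auto",
) -> list[ImageVolume]:
    """Adjoint-NUFFT reconstruction; returns one complex image per channel."""
    if acq.samples.shape[:2] != (traj.n_proj, traj.n_samples):
        raise ValueError(
            f"data shape {acq.samples.shape[:2]} does not match trajectory "
            f"({traj.n_proj}, {traj.n_samples})"
        )
    coords = traj.flat_coords()
    kmax = float(np.max(np.linalg.norm(coords, axis=1)))
    weights = traj.flat_dcf().astype(float)
    if hamming:
        weights = weights * hamming_radial(np.linalg.norm(coords, axis=1), kmax)
    images = []
    meta = {"hamming": hamming, "dcf": "analytic-shell"}
    for c in range(acq.samples.shape[2]):
        img = nufft.adjoint(
            acq.samples[..., c].reshape(-1), traj.geometry, coords, weights, method=method
        )
        images.append(ImageVolume(traj.geometry, img, acq.nucleus, dict(meta)))
    return images


def combine_channels(images: list[ImageVolume]) -> ImageVolume:
    """Root-sum-of-squares magnitude combination."""
    if len(images) == 0:
        raise ValueError("need at least one channel image")
    geom = images[0].geometry
    acc = np.zeros(geom.shape)
    for im in images:
        if im.geometry != geom:
            raise ValueError("channel geometries differ")
        acc += np.abs(im.data) ** 2
    return ImageVolume(geom, np.sqrt(acc), images[0].nucleus, {"combine": "rss"})


def resample_to(img: ImageVolume, target: GridGeometry) -> ImageVolume:
    """Trilinear resampling onto the voxel centers of ``target``.

    Out-of-FOV voxels are set to zero. Complex data are interpolated per
    real/imaginary part.
    """
    src = img.geometry
    # target voxel centers in source voxel-index coordinates
    tx, ty, tz = target.meshgrid()
    coords = np.stack(
        [
            (tx - src.origin[0]) / src.voxel_size[0],
            (ty - src.origin[1]) / src.voxel_size[1],
            (tz - src.origin[2]) / src.voxel_size[2],
        ]
    )
    def interp(arr):
        return map_coordinates(arr, coords, order=1, mode="constant", cval=0.0)

    if np.iscomplexobj(img.data):
        data = interp(img.data.real) + 1j * interp(img.data.imag)
    else:
        data = interp(img.data)
    return ImageVolume(target, data, img.nucleus, {**img.meta, "resampled_from": src.shape})


def rigid_translate(img: ImageVolume, shift_mm: tuple[float, float, float]) -> ImageVolume:
    """Rigid translation (trilinear); the only registration provided."""
    target = img.geometry
    xx, yy, zz = target.meshgrid()
    coords = np.stack(
        [
            (xx - shift_mm[0] - target.origin[0]) / target.voxel_size[0],
            (yy - shift_mm[1] - target.origin[1]) / target.voxel_size[1],
            (zz - shift_mm[2] - target.origin[2]) / target.voxel_size[2],
        ]
    )
    def interp(arr):
        return map_coordinates(arr, coords, order=1, mode="constant", cval=0.0)

    if np.iscomplexobj(img.data):
        data = interp(img.data.real) + 1j * interp(img.data.imag)
    else:
        data = interp(img.data)
    return ImageVolume(target, data, img.nucleus, dict(img.meta))


def relative_difference_map(
    x: ImageVolume, y: ImageVolume, mask: np.ndarray
) -> tuple[np.ndarray, float, int]:
    """Voxelwise (x - y)/y over ``mask``.

    Returns the map (NaN outside the valid mask), its mean over the valid
    voxels, and the number of voxels excluded because y == 0.
    """
    if x.geometry != y.geometry:
        raise ValueError("geometries differ")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != x.geometry.shape:
        raise ValueError("mask shape must match geometry")
    if not mask.any():
        raise ValueError("mask is empty")
    ydata = np.abs(y.data) if np.iscomplexobj(y.data) else y.data
    xdata = np.abs(x.data) if np.iscomplexobj(x.data) else x.data
    valid = mask & (ydata != 0)
    n_excluded = int(mask.sum() - valid.sum())
    out = np.full(x.geometry.shape, np.nan)
    out[valid] = (xdata[valid] - ydata[valid]) / ydata[valid]
    if not valid.any():
        raise ValueError("all masked voxels have y == 0")
    return out, float(np.mean(out[valid])), n_excluded
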