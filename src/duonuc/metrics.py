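"""Quantitative evaluation: Rayleigh-corrected SNR, noise estimation,
coefficient of variation, relative differences."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import GridGeometry

# magnitude-only (Rayleigh) noise: std_magnitude = sigma * sqrt((4 - pi)/2)
RAYLEIGH_STD_FACTOR = float(np.sqrt((4.0 - np.pi) / 2.0))


@dataclass(frozen=True)
class ROI:
    """Boolean region-of-interest mask on a grid."""

    geometry: GridGeometry
    mask: np.ndarray
    descriptor: str = ""

    def __post_init__(self):
        if self.mask.shape != self.geometry.shape:
            raise ValueError("mask shape must match geometry")


def central_box_roi(geometry: GridGeometry, dims_mm: tuple[float, float, float],
                    descriptor: str = "central box") -> ROI:
    """Axis-aligned box of the given physical dimensions at the grid center."""
    xx, yy, zz = geometry.meshgrid()
    m = (
        (np.abs(xx) <= dims_mm[0] / 2)
        & (np.abs(yy) <= dims_mm[1] / 2)
        & (np.abs(zz) <= dims_mm[2] / 2)
    )
    return ROI(geometry, m, descriptor)


def ellipsoid_roi(geometry: GridGeometry, center_mm, semi_axes_mm,
                  descriptor: str = "ellipsoid") -> ROI:
    xx, yy, zz = geometry.meshgrid()
    cx, cy, cz = center_mm
    ax, ay, az = semi_axes_mm
    m = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + ((zz - cz) / az) ** 2 <= 1.0
    return ROI(geometry, m, descriptor)


def noise_sigma_from_scans(noise_magnitudes: np.ndarray) -> dict:
    """Noise level from magnitude-only noise scans.

    Returns both the raw magnitude standard deviation (``std_noise``) and
    the Gaussian-equivalent sigma ``std_noise / sqrt((4 - pi)/2)``.
    """
    vals = np.abs(np.asarray(noise_magnitudes)).ravel()
    if vals.size < 100:
        warnings.warn(f"only {vals.size} noise samples; estimate may be unstable")
    std = float(np.std(vals))
    return {"std_noise": std, "sigma_gaussian": std / RAYLEIGH_STD_FACTOR}


def snr_map(image_magnitude: np.ndarray, std_noise: float) -> np.ndarray:
    """Rayleigh-corrected SNR: SNR(x) = image(x)/std_noise * sqrt((4-pi)/2)."""
    if std_noise <= 0:
        raise ValueError("std_noise must be > 0")
    return np.abs(np.asarray(image_magnitude)) / std_noise * RAYLEIGH_STD_FACTOR


def cv(values: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Coefficient of variation: population std / mean over the ROI."""
    vals = np.asarray(values, dtype=float)
    if mask is not None:
        vals = vals[np.asarray(mask, dtype=bool)]
    vals = vals.ravel()
    if vals.size == 0:
        raise ValueError("ROI is empty")
    mean = float(np.mean(vals))
    if mean == 0:
        raise ValueError("mean over ROI is zero; CV undefined")
    return float(np.std(vals) / mean)


def mean_relative_difference(
    x: np.ndarray, y: np.ndarray, mask: np.ndarray
) -> tuple[float, float]:
    """Mean and std of (x - y)/y over the mask (y == 0 voxels excluded)."""
    x = np.abs(np.asarray(x, dtype=np.complex128)) if np.iscomplexobj(x) else np.asarray(x, float)
    y = np.abs(np.asarray(y, dtype=np.complex128)) if np.iscomplexobj(y) else np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("shapes differ")
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("mask is empty")
    valid = m & (y != 0)
    if not valid.any():
        raise ValueError("all masked voxels have y == 0")
    rel = (x[valid] - y[valid]) / y[valid]
    return float(np.mean(rel)), float(np.std(rel))
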