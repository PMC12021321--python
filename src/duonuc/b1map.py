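"""Flip-angle and RF field mapping.

Implements the double-angle method (FA = arccos(S_2a / 2 S_a)), actual
flip-angle imaging (AFI; FA = arccos((rn - 1)/(n - r)) with n = TR_long /
TR_short and r the steady-state signal ratio), relative receive (B1-) maps
from signal / sin(FA), transmit efficiency eta = FA / (2 pi gamma T_pulse
U_applied) in nT/V, relative channel-wise transmit maps, small-tip flip-angle
simulation from channel maps under a pTx pulse, and ROI-mean normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import GridGeometry
from .phantom import GAMMA_MHZ_PER_T, ChannelFieldSet
from .recon import ImageVolume

# B1- validity window: sin(FA) blows up outside it
FA_VALID_MIN_DEG = 5.0
FA_VALID_MAX_DEG = 175.0


@dataclass(frozen=True)
class FAMap:
    geometry: GridGeometry
    fa: np.ndarray  # degrees
    nominal_fa: float  # degrees
    valid: np.ndarray  # bool mask

    def __post_init__(self):
        if self.fa.shape != self.geometry.shape or self.valid.shape != self.geometry.shape:
            raise ValueError("fa/valid shape must match geometry")
        v = self.fa[self.valid]
        if v.size and (np.min(v) < -1e-9 or np.max(v) > 180 + 1e-9):
            raise ValueError("valid flip angles must lie in [0, 180] degrees")


@dataclass(frozen=True)
class EfficiencyMap:
    geometry: GridGeometry
    eta_nt_per_v: np.ndarray
    u_applied: float  # V
    t_pulse: float  # ms
    gamma_mhz_per_t: float


def fa_map_double_angle(img_alpha: ImageVolume, img_2alpha: ImageVolume) -> FAMap:
    """Double-angle FA map: FA = arccos(S_2a / (2 S_a)) voxelwise.

    Assumes full T1 recovery (long TR). Voxels with S_a = 0 or |ratio| > 1
    are masked invalid.
    """
    if img_alpha.geometry != img_2alpha.geometry:
        raise ValueError("geometries differ")
    s1 = np.abs(img_alpha.data).astype(float)
    s2 = np.abs(img_2alpha.data).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = s2 / (2.0 * s1)
    valid = (s1 > 0) & np.isfinite(ratio) & (np.abs(ratio) <= 1.0)
    fa = np.zeros(s1.shape)
    fa[valid] = np.rad2deg(np.arccos(ratio[valid]))
    return FAMap(img_alpha.geometry, fa, float("nan"), valid)


def fa_map_afi(
    img_tr_long: ImageVolume,
    img_tr_short: ImageVolume,
    tr_long: float,
    tr_short: float,
) -> FAMap:
    """AFI flip-angle map from the two interleaved-TR steady-state images.

    ``img_tr_long`` is the image whose excitation follows the long delay,
    ``img_tr_short`` the one following the short delay. With
    n = tr_long/tr_short and r = S_short/S_long,
    FA = arccos((r n - 1)/(n - r)), valid to first order in TR/T1.
    """
    if img_tr_long.geometry != img_tr_short.geometry:
        raise ValueError("geometries differ")
    if not tr_long > tr_short > 0:
        raise ValueError("need tr_long > tr_short > 0")
    s_long = np.abs(img_tr_long.data).astype(float)
    s_short = np.abs(img_tr_short.data).astype(float)
    n = tr_long / tr_short
    with np.errstate(divide="ignore", invalid="ignore"):
        r = s_short / s_long
        arg = (r * n - 1.0) / (n - r)
    valid = (s_long > 0) & np.isfinite(arg) & (np.abs(arg) <= 1.0)
    fa = np.zeros(s_long.shape)
    fa[valid] = np.rad2deg(np.arccos(arg[valid]))
    return FAMap(img_tr_long.geometry, fa, float("nan"), valid)


def afi_steady_state_signals(
    fa_deg: float | np.ndarray, tr_long: float, tr_short: float, t1: float
) -> tuple[np.ndarray, np.ndarray]:
    """Exact two-TR steady-state signals (S_after_long, S_after_short).

    Longitudinal magnetization alternates between M_long (just before the
    pulse that follows the long delay) and M_short; signals are M sin(FA).
    """
    c = np.cos(np.deg2rad(fa_deg))
    s = np.sin(np.deg2rad(fa_deg))
    e_s = np.exp(-tr_short / t1)
    e_l = np.exp(-tr_long / t1)
    m_long = (c * e_l * (1.0 - e_s) + (1.0 - e_l)) / (1.0 - c * c * e_s * e_l)
    m_short = c * e_s * m_long + (1.0 - e_s)
    return m_long * s, m_short * s


def b1_minus_map(
    signal: ImageVolume, fa: FAMap, fa_min_deg: float = FA_VALID_MIN_DEG
) -> ImageVolume:
    """Relative receive-field map: B1-(x) ~ S(x)/sin(FA(x)), mean-1 normalized.

    Voxels with FA outside [fa_min_deg, 180 - fa_min_deg] or invalid FA are
    masked (set to NaN).
    """
    if signal.geometry != fa.geometry:
        raise ValueError("geometries differ")
    s = np.abs(signal.data).astype(float)
    valid = fa.valid & (fa.fa >= fa_min_deg) & (fa.fa <= 180.0 - fa_min_deg)
    if not valid.any():
        raise ValueError("no valid voxels for B1- mapping")
    out = np.full(s.shape, np.nan)
    out[valid] = s[valid] / np.sin(np.deg2rad(fa.fa[valid]))
    out[valid] /= np.mean(out[valid])
    return ImageVolume(signal.geometry, out, signal.nucleus, {"map": "b1minus", "norm": "mean1"})


def b1_plus_efficiency(
    fa: FAMap, t_pulse_ms: float, u_applied: float, gamma_mhz_per_t: float
) -> EfficiencyMap:
    """Transmit efficiency eta(x) = FA_rad(x) / (2 pi gamma T_pulse U), nT/V."""
    if t_pulse_ms <= 0 or u_applied <= 0 or gamma_mhz_per_t <= 0:
        raise ValueError("t_pulse, u_applied and gamma must be > 0")
    gamma_hz = gamma_mhz_per_t * 1e6
    t_s = t_pulse_ms * 1e-3
    eta_t_per_v = np.deg2rad(fa.fa) / (2.0 * np.pi * gamma_hz * t_s * u_applied)
    return EfficiencyMap(fa.geometry, eta_t_per_v * 1e9, u_applied, t_pulse_ms, gamma_mhz_per_t)


def relative_channel_maps(channel_images: list[ImageVolume]) -> tuple[np.ndarray, np.ndarray]:
    """Relative complex per-channel transmit maps.

    map_c(x) = img_c(x) / sum_c |img_c(x)|, so sum_c |map_c| = 1 on valid
    voxels. Returns (maps of shape (n_ch, *shape), valid mask).
    """
    if len(channel_images) < 2:
        raise ValueError("need at least 2 channel images")
    geom = channel_images[0].geometry
    stack = np.stack([np.asarray(im.data, dtype=np.complex128) for im in channel_images])
    for im in channel_images:
        if im.geometry != geom:
            raise ValueError("channel geometries differ")
    denom = np.sum(np.abs(stack), axis=0)
    valid = denom > 0
    maps = np.zeros_like(stack)
    maps[:, valid] = stack[:, valid] / denom[valid]
    return maps, valid


def simulate_fa_map(
    fields: ChannelFieldSet,
    pulse,
    reference_voltage: float,
    gamma_mhz_per_t: float | None = None,
) -> FAMap:
    """Small-tip flip-angle map produced by a pTx pulse on channel maps.

    For a static shim with per-channel complex weights w_c:
        FA_rad(x) = 2 pi gamma |sum_c w_c B1c+(x)| U_ref T_pulse.
    For a kT-points pulse with sub-pulse weights w_{k,c}, blips kappa_k
    (1/mm) and sub-pulse durations T_k:
        FA_rad(x) = 2 pi gamma U_ref |sum_k T_k (sum_c w_{k,c} B1c+(x))
                     exp(2 pi i kappa_k . x)|.
    Fields are in nT/V.
    """
    from .ptx import KTPulse, ShimSolution  # local import to avoid cycle

    if gamma_mhz_per_t is None:
        gamma_mhz_per_t = GAMMA_MHZ_PER_T[fields.nucleus]
    gamma_hz = gamma_mhz_per_t * 1e6
    geom = fields.geometry
    if isinstance(pulse, ShimSolution):
        combined = np.tensordot(pulse.weights, fields.tx_fields, axes=(0, 0))
        t_total_s = pulse.t_pulse_ms * 1e-3
        fa_rad = 2.0 * np.pi * gamma_hz * np.abs(combined) * 1e-9 * reference_voltage * t_total_s
    elif isinstance(pulse, KTPulse):
        xx, yy, zz = geom.meshgrid()
        acc = np.zeros(geom.shape, dtype=np.complex128)
        t_sub_s = np.asarray(pulse.subpulse_durations_ms) * 1e-3
        for k in range(pulse.K):
            sub = np.tensordot(pulse.weights[k], fields.tx_fields, axes=(0, 0))
            kx, ky, kz = pulse.blips[k]
            phase = np.exp(2j * np.pi * (kx * xx + ky * yy + kz * zz))
            acc += t_sub_s[k] * sub * phase
        fa_rad = 2.0 * np.pi * gamma_hz * np.abs(acc) * 1e-9 * reference_voltage
    else:
        raise TypeError(f"unsupported pulse type {type(pulse).__name__}")
    fa = np.rad2deg(fa_rad)
    # the small-tip model is linear and unbounded; angles beyond 180 deg are
    # outside its validity and are masked rather than clipped
    valid = fa <= 180.0
    return FAMap(geom, np.where(valid, fa, 0.0), float("nan"), valid)


def normalize_fa(fa: FAMap, roi_mask: np.ndarray) -> FAMap:
    """Normalize a FA map to unit mean over an ROI (e.g. the heart)."""
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != fa.geometry.shape:
        raise ValueError("roi shape must match geometry")
    sel = roi & fa.valid
    if not sel.any():
        raise ValueError("roi is empty (or fully invalid)")
    mean = float(np.mean(fa.fa[sel]))
    if mean == 0:
        raise ValueError("mean FA over roi is zero")
    return FAMap(fa.geometry, fa.fa / mean, fa.nominal_fa, fa.valid.copy())
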