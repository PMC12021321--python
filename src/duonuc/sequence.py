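"""Interleaved dual-nuclear event scheduling, steady-state signal model and
forward k-space simulation.

One sodium repetition time hosts the sodium excitation/readout plus
``n_h_per_tr`` proton excitations fit into the idle time; with four proton
events per period the proton TR pattern is (tr_a, tr_a, tr_a, tr_b) where
``tr_b = tr_na - 3 tr_a`` absorbs the sodium block. A spoiled-GRE steady
state is assumed for both nuclei, with T2* decay applied as a single
``exp(-TE/T2*)`` factor at the echo time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from . import nufft
from .geometry import GridGeometry
from .phantom import ChannelFieldSet, Nucleus, PhantomVolume
from .trajectory import TrajectorySet


@dataclass(frozen=True)
class SequenceParams:
    """Excitation/readout parameters for one nucleus (times in ms)."""

    nucleus: Nucleus
    nominal_fa: float  # degrees
    tr: float  # ms; for the proton train this is tr_a, tr_b is derived
    te: float
    t_pulse: float
    t_ro: float
    n_proj: int

    def __post_init__(self):
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if self.te < self.t_pulse / 2:
            raise ValueError("te must be >= t_pulse/2")
        if self.n_proj < 1:
            raise ValueError("n_proj must be >= 1")
        if not 0 <= self.nominal_fa <= 180:
            raise ValueError("nominal_fa must be in [0, 180] degrees")


@dataclass(frozen=True)
class ScheduledEvent:
    t_start: float  # ms
    nucleus: Nucleus
    projection_index: int
    tr_class: Literal["a", "b", "na"]


@dataclass(frozen=True)
class InterleaveSchedule:
    events: tuple[ScheduledEvent, ...]
    n_h_per_tr: int
    tr_na: float  # ms
    tr_a: float  # ms
    tr_b: float  # ms
    total_duration: float  # s

    def events_for(self, nucleus: Nucleus) -> list[ScheduledEvent]:
        return [e for e in self.events if e.nucleus == nucleus]

    def count(self, nucleus: Nucleus) -> int:
        return sum(1 for e in self.events if e.nucleus == nucleus)


@dataclass(frozen=True)
class AcquiredData:
    """Simulated multi-channel k-space data for one nucleus."""

    samples: np.ndarray  # (n_proj, n_samples, n_rx) complex
    nucleus: Nucleus
    noise_sigma: float
    seed: Optional[int]


def build_interleaved_schedule(
    params_na: SequenceParams,
    params_h: SequenceParams,
    n_h_per_tr: int = 4,
    h_order: str = "aaab",
) -> InterleaveSchedule:
    """Interleave ``n_h_per_tr`` proton excitations into each sodium TR.

    ``params_h.tr`` is interpreted as tr_a; tr_b = tr_na - (n_h_per_tr-1)*tr_a
    absorbs the sodium excitation/readout block. ``h_order`` places the long
    TR last ('aaab') or first ('baaa') within each period.
    """
    if n_h_per_tr < 0:
        raise ValueError("n_h_per_tr must be >= 0")
    if params_h.n_proj != n_h_per_tr * params_na.n_proj:
        raise ValueError(
            f"proton projection count {params_h.n_proj} != "
            f"{n_h_per_tr} * {params_na.n_proj}"
        )
    if h_order not in ("aaab", "baaa"):
        raise ValueError("h_order must be 'aaab' or 'baaa'")
    tr_na = params_na.tr
    tr_a = params_h.tr
    tr_b = tr_na - (n_h_per_tr - 1) * tr_a if n_h_per_tr > 0 else tr_na
    if n_h_per_tr > 0 and tr_b <= 0:
        raise ValueError("proton TRs do not fit into the sodium TR")
    events: list[ScheduledEvent] = []
    h_idx = 0
    for p in range(params_na.n_proj):
        t0 = p * tr_na
        events.append(ScheduledEvent(t0, "na", p, "na"))
        # proton events start after the sodium excitation+readout block
        t_block = params_na.te + params_na.t_ro
        t = t0 + t_block
        for j in range(n_h_per_tr):
            if h_order == "aaab":
                cls = "b" if j == n_h_per_tr - 1 else "a"
            else:
                cls = "b" if j == 0 else "a"
            events.append(ScheduledEvent(t, "h", h_idx, cls))
            t += tr_b if cls == "b" else tr_a
            h_idx += 1
    total = params_na.n_proj * tr_na / 1000.0
    return InterleaveSchedule(tuple(events), n_h_per_tr, tr_na, tr_a, tr_b, total)


def single_nuclear_schedule(params: SequenceParams) -> InterleaveSchedule:
    """Schedule with only one nucleus (other transmissions switched off)."""
    events = tuple(
        ScheduledEvent(p * params.tr, params.nucleus, p, "na" if params.nucleus == "na" else "a")
        for p in range(params.n_proj)
    )
    return InterleaveSchedule(
        events,
        0,
        params.tr,
        params.tr,
        params.tr,
        params.n_proj * params.tr / 1000.0,
    )


def protocol_duration(n_proj: int, tr_ms: float) -> float:
    """Duration in seconds of a protocol of n_proj repetitions of tr_ms."""
    return n_proj * tr_ms / 1000.0


def format_min_s(seconds: float) -> str:
    """Format a duration as the conventional min:s string (e.g. 900 -> '15:00')."""
    m, s = divmod(int(round(seconds)), 60)
    return f"{m}:{s:02d}"


def spgr_signal(
    m0: np.ndarray | float,
    fa_deg: np.ndarray | float,
    tr: float,
    t1: np.ndarray | float,
    te: float = 0.0,
    t2star: np.ndarray | float = np.inf,
) -> np.ndarray | float:
    """Spoiled gradient-echo steady-state signal.

    S = m0 sin(fa) (1 - E1) / (1 - cos(fa) E1) * exp(-te/t2star),
    E1 = exp(-tr/t1).
    """
    fa = np.deg2rad(fa_deg)
    e1 = np.exp(-tr / np.asarray(t1, dtype=float))
    decay = np.exp(-te / np.asarray(t2star, dtype=float))
    return m0 * np.sin(fa) * (1.0 - e1) / (1.0 - np.cos(fa) * e1) * decay


def ernst_angle(tr: float, t1: float) -> float:
    """Flip angle (degrees) maximizing the spoiled-GRE signal."""
    return float(np.rad2deg(np.arccos(np.exp(-tr / t1))))


def simulate_acquisition(
    phantom: PhantomVolume,
    fields: ChannelFieldSet,
    traj: TrajectorySet,
    params: SequenceParams,
    fa_map_deg: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    method: str = "auto",
    schedule: InterleaveSchedule | None = None,
) -> AcquiredData:
    """Forward-simulate multi-channel radial k-space data for one nucleus.

    The transverse magnetization is the spoiled-GRE steady state evaluated
    with the voxelwise flip angle (``fa_map_deg``; defaults to the nominal
    flip angle everywhere), weighted by each receive field, and sampled with
    the nonuniform Fourier transform at the trajectory coordinates. I.i.d.
    complex Gaussian noise of standard deviation ``noise_sigma`` per real
    component is added per channel. Nuclei are simulated independently (no
    cross-talk), so interleaved and single-nuclear schedules yield identical
    per-nucleus data for the same seed; a ``schedule`` may be passed for
    bookkeeping and is only checked for projection-count consistency.
    """
    if schedule is not None and schedule.count(phantom.nucleus) not in (0, traj.n_proj):
        raise ValueError("schedule projection count does not match trajectory")
    if phantom.geometry != fields.geometry:
        raise ValueError("phantom and field geometries differ")
    if phantom.geometry != traj.geometry:
        raise ValueError("phantom and trajectory geometries differ")
    if fa_map_deg is None:
        fa_map_deg = np.full(phantom.geometry.shape, params.nominal_fa)
    elif fa_map_deg.shape != phantom.geometry.shape:
        raise ValueError("fa_map_deg shape must match geometry")
    mxy = spgr_signal(
        phantom.m0, fa_map_deg, params.tr, phantom.t1_map, params.te, phantom.t2star_map
    )
    coords = traj.flat_coords()
    n_rx = fields.n_rx
    out = np.empty((traj.n_proj, traj.n_samples, n_rx), dtype=np.complex128)
    for c in range(n_rx):
        weighted = mxy * fields.rx_fields[c]
        out[..., c] = nufft.forward(weighted, phantom.geometry, coords, method=method).reshape(
            traj.n_proj, traj.n_samples
        )
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sigma, out.shape + (2,))
        out = out + noise[..., 0] + 1j * noise[..., 1]
    return AcquiredData(out, phantom.nucleus, float(noise_sigma), seed)


def simulate_noise_scan(
    n_samples: int, n_rx: int, noise_sigma: float, seed: int | None = None
) -> np.ndarray:
    """Noise-only complex samples (excitation off), shape (n_samples, n_rx)."""
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sigma, (n_samples, n_rx, 2))
    return noise[..., 0] + 1j * noise[..., 1]


def time_averaged_power(
    pulse_voltages: Sequence[float] | np.ndarray,
    t_pulse_ms: float,
    schedule: InterleaveSchedule,
    nucleus: Nucleus = "h",
    impedance_ohm: float = 50.0,
    limit_w: float = 1.195,
) -> tuple[np.ndarray, bool]:
    """Per-channel time-averaged RF power for rectangular hard pulses.

    P_c = duty * U_c^2 / (2 Z) with duty = n_pulses * t_pulse / duration.
    Returns the per-channel powers (W) and whether all satisfy ``limit_w``.
    """
    if impedance_ohm <= 0:
        raise ValueError("impedance must be > 0")
    u = np.abs(np.asarray(pulse_voltages, dtype=float))
    n_pulses = schedule.count(nucleus)
    duty = n_pulses * (t_pulse_ms / 1000.0) / schedule.total_duration
    power = duty * u**2 / (2.0 * impedance_ohm)
    return power, bool(np.all(power <= limit_w))
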