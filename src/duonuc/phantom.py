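"""Digital torso phantoms and phenomenological coil field maps.

The phantoms are voxelized ellipsoid compartments (a homogeneous torso-like
body, optionally nested heart/blood compartments) carrying per-nucleus
magnetization density (proportional to concentration for sodium), T1 and T2*.

Field maps are phenomenological stand-ins for the hardware of interest: a
single-channel volume (birdcage-like) sodium coil with an optional corner
drop-off, and an 8-channel proton transceiver array with four loop-like
elements anterior and four posterior. They are meant to exercise the mapping
and pulse-design math, not to approximate Maxwell's equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .geometry import GridGeometry

Nucleus = Literal["na", "h"]

# gyromagnetic ratios, MHz/T
GAMMA_MHZ_PER_T = {"h": 42.577, "na": 11.262}

# defaults: torso phantom concentration from the in vitro setup; heart/blood
# values are illustrative in vivo-like placeholders (blood ~140 mM plasma
# sodium, myocardium lower due to the extracellular volume fraction)
TORSO_CONC_MM = 300.0
BLOOD_CONC_MM = 140.0
MYOCARDIUM_CONC_MM = 43.0


@dataclass(frozen=True)
class CompartmentSpec:
    """Ellipsoidal compartment with MR properties.

    Later compartments in a list take priority (painter's order).
    """

    name: str
    center: tuple[float, float, float]  # mm
    semi_axes: tuple[float, float, float]  # mm
    concentration: float  # mM (used as m0 for sodium)
    t1: float  # ms
    t2star: float  # ms
    proton_density: float = 1.0  # arbitrary units (used as m0 for 1H)

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.t1 <= 0 or self.t2star <= 0:
            raise ValueError("t1 and t2star must be > 0")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi_axes must be > 0")

    def mask(self, geometry: GridGeometry) -> np.ndarray:
        """Voxel-center-in-ellipsoid boolean mask."""
        xx, yy, zz = geometry.meshgrid()
        cx, cy, cz = self.center
        ax, ay, az = self.semi_axes
        r2 = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + ((zz - cz) / az) ** 2
        return r2 <= 1.0


@dataclass(frozen=True)
class PhantomVolume:
    """Voxelized magnetization density and relaxation maps for one nucleus."""

    geometry: GridGeometry
    m0: np.ndarray
    t1_map: np.ndarray
    t2star_map: np.ndarray
    nucleus: Nucleus

    def __post_init__(self):
        for arr in (self.m0, self.t1_map, self.t2star_map):
            if arr.shape != self.geometry.shape:
                raise ValueError("phantom maps must match geometry shape")
        if np.any(self.m0 < 0):
            raise ValueError("m0 must be >= 0")

    @property
    def support(self) -> np.ndarray:
        return self.m0 > 0


@dataclass(frozen=True)
class ChannelFieldSet:
    """Complex per-channel transmit (nT/V) and receive (relative) maps."""

    geometry: GridGeometry
    tx_fields: np.ndarray  # (n_tx, *shape) complex, nT/V
    rx_fields: np.ndarray  # (n_rx, *shape) complex, relative
    nucleus: Nucleus

    def __post_init__(self):
        if self.tx_fields.ndim != 4 or self.tx_fields.shape[1:] != self.geometry.shape:
            raise ValueError("tx_fields must be (n_tx, *geometry.shape)")
        if self.rx_fields.ndim != 4 or self.rx_fields.shape[1:] != self.geometry.shape:
            raise ValueError("rx_fields must be (n_rx, *geometry.shape)")
        if not (np.all(np.isfinite(self.tx_fields)) and np.all(np.isfinite(self.rx_fields))):
            raise ValueError("fields must be finite")

    @property
    def n_tx(self) -> int:
        return self.tx_fields.shape[0]

    @property
    def n_rx(self) -> int:
        return self.rx_fields.shape[0]


def default_torso_compartments(geometry: GridGeometry, nucleus: Nucleus = "na"):
    """Homogeneous torso ellipsoid filling ~80% of the FOV."""
    fov = geometry.fov
    semi = tuple(0.4 * f for f in fov)
    if nucleus == "na":
        return [CompartmentSpec("torso", (0.0, 0.0, 0.0), semi, TORSO_CONC_MM, 35.0, 18.0)]
    return [
        CompartmentSpec("torso", (0.0, 0.0, 0.0), semi, TORSO_CONC_MM, 1200.0, 40.0, 1.0)
    ]


def default_cardiac_compartments(geometry: GridGeometry) -> list[CompartmentSpec]:
    """Torso body + myocardium shell + blood pool (painter's order)."""
    fov = geometry.fov
    body = tuple(0.4 * f for f in fov)
    heart = tuple(0.16 * f for f in fov)
    blood = tuple(0.09 * f for f in fov)
    off = (0.08 * fov[0], -0.05 * fov[1], 0.0)
    return [
        CompartmentSpec("body", (0.0, 0.0, 0.0), body, 20.0, 35.0, 18.0, 0.7),
        CompartmentSpec("myocardium", off, heart, MYOCARDIUM_CONC_MM, 35.0, 15.0, 0.8),
        CompartmentSpec("blood", off, blood, BLOOD_CONC_MM, 35.0, 20.0, 1.0),
    ]


def make_torso_phantom(
    geometry: GridGeometry,
    compartments: Sequence[CompartmentSpec],
    nucleus: Nucleus = "na",
) -> PhantomVolume:
    """Voxelize compartments onto the grid; later compartments override."""
    if len(compartments) == 0:
        raise ValueError("compartment list must be non-empty")
    m0 = np.zeros(geometry.shape)
    t1 = np.full(geometry.shape, 1.0)
    t2s = np.full(geometry.shape, 1.0)
    for comp in compartments:
        m = comp.mask(geometry)
        m0[m] = comp.concentration if nucleus == "na" else comp.proton_density
        t1[m] = comp.t1
        t2s[m] = comp.t2star
    return PhantomVolume(geometry, m0, t1, t2s, nucleus)


def make_birdcage_field(
    geometry: GridGeometry,
    mode: Literal["uniform", "asymmetric"] = "asymmetric",
    asymmetry: float = 0.5,
    amplitude: float = 100.0,
) -> ChannelFieldSet:
    """Single-channel volume-coil field (nT/V) with optional corner drop-off.

    ``asymmetry=0`` (or mode='uniform') gives a perfectly flat field. For
    asymmetric mode a smooth linear + quadratic taper reduces the field
    toward the +x/+y (upper-left on a coronal view) corner; ``asymmetry``
    scales the depth of the drop-off, so the ROI coefficient of variation is
    monotone in it.
    """
    if asymmetry < 0:
        raise ValueError("asymmetry must be >= 0")
    if mode == "uniform":
        asymmetry = 0.0
    xx, yy, _ = geometry.meshgrid()
    fx, fy, _ = geometry.fov
    u = (xx / fx) + (yy / fy)  # in [-1, 1] across the diagonal
    taper = 1.0 - asymmetry * (0.35 * (u + 1.0) / 2.0 + 0.35 * ((u + 1.0) / 2.0) ** 2)
    field = amplitude * np.clip(taper, 0.05, None)
    tx = field[None].astype(np.complex128)
    rx = (field / amplitude)[None].astype(np.complex128)
    return ChannelFieldSet(geometry, tx, rx, "na")


def make_array_fields(
    geometry: GridGeometry,
    n_ch: int = 8,
    layout: str = "anterior_posterior",
    decay_mm: float | None = None,
    seed: int | None = None,
    phase_jitter: float = 0.0,
) -> ChannelFieldSet:
    """Loop-array transceiver fields: 4 anterior + 4 posterior channels.

    Magnitudes decay exponentially with distance from each loop center;
    phases ramp smoothly away from the loop plus a per-channel offset chosen
    so the default zero-phase (vendor-like) combination interferes
    destructively mid-torso. ``phase_jitter`` (radians) adds seeded
    per-channel random phase/position perturbations to emulate inter-subject
    variability for shim-library synthesis.
    """
    if n_ch < 2:
        raise ValueError("n_ch must be >= 2")
    if layout != "anterior_posterior":
        raise ValueError(f"unknown layout {layout!r}")
    rng = np.random.default_rng(seed)
    fov = geometry.fov
    if decay_mm is None:
        decay_mm = 0.45 * min(fov)
    xx, yy, zz = geometry.meshgrid()
    n_ant = (n_ch + 1) // 2
    n_post = n_ch - n_ant
    centers = []
    for i in range(n_ant):  # anterior: above the chest (+y)
        x = (-0.5 + (i + 0.5) / n_ant) * 0.8 * fov[0]
        centers.append((x, 0.55 * fov[1], 0.0))
    for i in range(n_post):  # posterior: below the back (-y)
        x = (-0.5 + (i + 0.5) / n_post) * 0.8 * fov[0]
        centers.append((x, -0.55 * fov[1], 0.0))
    fields = np.empty((n_ch,) + geometry.shape, dtype=np.complex128)
    for c, (cx, cy, cz) in enumerate(centers):
        jit = rng.normal(0.0, phase_jitter * 10.0, 3) if phase_jitter > 0 else np.zeros(3)
        d = np.sqrt((xx - cx - jit[0]) ** 2 + (yy - cy - jit[1]) ** 2 + (zz - cz - jit[2]) ** 2)
        mag = np.exp(-d / decay_mm)
        # smooth spatial phase ramp + per-channel offset: offsets are evenly
        # spread over 2 pi so the unshimmed sum cancels near mid-torso
        phase = 2.0 * np.pi * c / n_ch + 0.5 * np.pi * d / max(fov)
        if phase_jitter > 0:
            phase = phase + rng.normal(0.0, phase_jitter)
        fields[c] = mag * np.exp(1j * phase)
    # normalize so the sum of magnitudes is O(1) at grid center
    center_idx = tuple(s // 2 for s in geometry.shape)
    norm = np.sum(np.abs(fields[(slice(None),) + center_idx]))
    fields *= 1.0 / norm
    return ChannelFieldSet(geometry, 100.0 * fields, fields.copy(), "h")
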