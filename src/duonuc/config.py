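"""Run configuration with protocol defaults.

The default values mirror the acquisition-parameter table of the protocol
this package emulates: interleaved sodium/proton imaging (sodium: 6 mm
nominal resolution, FA 82 deg, TR 60 ms, TE 1.15 ms, 2 ms pulse, 5 ms
readout, 15000 half projections; proton: 2 mm, FA 10 deg, TR_a 13.08 ms /
TR_b 20.76 ms, TE 2.5 ms, 2 ms readout, 60000 full projections), the sodium
double-angle protocol (12 mm, FA 45/90, 4000 projections, TR 250 ms), the
proton AFI protocol (4 mm, FA 70, 7500 projections, TR 75/15 ms) and the
relative channel-wise transmit mapping (4 mm, FA 8, 10000 projections,
TR 4.5 ms, 8 channels).

Simulation sizes (grid, projection counts actually simulated) are separate
"sim" keys so the timing arithmetic can use the protocol counts while the
forward simulation stays desk-scale.
"""

from __future__ import annotations

import copy
from typing import Any

DEFAULT_CONFIG: dict[str, Any] = {
    "interleaved": {
        "na": {
            "resolution_mm": 6.0,
            "nominal_fa_deg": 82.0,
            "tr_ms": 60.0,
            "te_ms": 1.15,
            "t_pulse_ms": 2.0,
            "t_ro_ms": 5.0,
            "n_proj": 15000,
            "readout": "half",
        },
        "h": {
            "resolution_mm": 2.0,
            "nominal_fa_deg": 10.0,
            "tr_a_ms": 13.08,
            "tr_b_ms": 20.76,
            "te_ms": 2.5,
            "t_pulse_ms": 2.0,
            "t_ro_ms": 2.0,
            "n_proj": 60000,
            "readout": "full",
        },
        "n_h_per_tr": 4,
    },
    "na_double_angle": {
        "resolution_mm": 12.0,
        "fa_deg": [45.0, 90.0],
        "tr_ms": 250.0,
        "te_ms": 1.15,
        "t_pulse_ms": 2.0,
        "t_ro_ms": 5.0,
        "n_proj": 4000,
    },
    "h_afi": {
        "resolution_mm": 4.0,
        "fa_deg": 70.0,
        "tr_long_ms": 75.0,
        "tr_short_ms": 15.0,
        "te_ms": 3.03,
        "t_pulse_ms": 1.0,
        "t_ro_ms": 2.5,
        "n_proj": 7500,
    },
    "h_rel_b1": {
        "resolution_mm": 4.0,
        "fa_deg": 8.0,
        "tr_ms": 4.5,
        "te_ms": 2.02,
        "t_pulse_ms": 0.5,
        "t_ro_ms": 2.5,
        "n_proj": 10000,
        "n_channels": 8,
    },
    "hardware": {
        "power_limit_w": 1.195,
        "impedance_ohm": 50.0,
        "uref_slope_v_per_kg": 9.4,
        "uref_intercept_v": 542.5,
    },
    # scaled-down forward-simulation sizes; sample counts keep the radial
    # spacing below 1/FOV so the quadrature resolves the object spectrum
    "sim": {
        "grid_n": 24,
        "voxel_mm": 6.0,
        "n_proj_na": 400,
        "n_samples_na": 112,
        "n_proj_h": 1600,
        "n_samples_h": 113,
        "noise_sigma": 0.0,
        "seed": 0,
    },
}


class ConfigError(ValueError):
    pass


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def _require(cond: bool, path: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{path}: {msg}")


def validate_config(cfg: dict) -> dict:
    """Schema/physics validation; raises ConfigError naming the key path."""
    for key in ("interleaved", "sim"):
        _require(key in cfg, key, "missing section")
    na = cfg["interleaved"]["na"]
    h = cfg["interleaved"]["h"]
    for path, sec in (("interleaved.na", na), ("interleaved.h", h)):
        fa = sec["nominal_fa_deg"]
        _require(0 <= fa <= 180, f"{path}.nominal_fa_deg", f"flip angle {fa} outside [0, 180]")
        _require(sec["resolution_mm"] > 0, f"{path}.resolution_mm", "must be > 0")
        _require(sec["n_proj"] >= 1, f"{path}.n_proj", "must be >= 1")
    _require(na["tr_ms"] > 0, "interleaved.na.tr_ms", f"TR {na['tr_ms']} must be > 0")
    _require(h["tr_a_ms"] > 0, "interleaved.h.tr_a_ms", "must be > 0")
    n_per = cfg["interleaved"]["n_h_per_tr"]
    _require(n_per >= 0, "interleaved.n_h_per_tr", "must be >= 0")
    _require(
        h["n_proj"] == n_per * na["n_proj"],
        "interleaved.h.n_proj",
        f"must equal n_h_per_tr * na.n_proj = {n_per * na['n_proj']}",
    )
    sim = cfg["sim"]
    _require(sim["grid_n"] >= 4, "sim.grid_n", "must be >= 4")
    _require(sim["noise_sigma"] >= 0, "sim.noise_sigma", "must be >= 0")
    return cfg


def merge_config(base: dict, override: dict) -> dict:
    """Deep-merge override into a copy of base."""
    out = copy.deepcopy(base)

    def rec(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                rec(dst[k], v)
            else:
                dst[k] = v

    rec(out, override)
    return out
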