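"""File I/O: NIfTI volumes via nibabel, NPZ k-space containers, YAML specs."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .geometry import GridGeometry
from .phantom import CompartmentSpec
from .recon import ImageVolume


def write_nifti(img: ImageVolume, path) -> None:
    """Write a volume as NIfTI; complex data become a magnitude/phase pair.

    For complex input, files ``<stem>_mag.nii.gz``-style naming is avoided:
    magnitude and phase are stacked along a 4th axis instead.
    """
    affine = np.diag(list(img.geometry.voxel_size) + [1.0])
    affine[:3, 3] = img.geometry.origin
    if np.iscomplexobj(img.data):
        data = np.stack([np.abs(img.data), np.angle(img.data)], axis=-1)
    else:
        data = np.asarray(img.data, dtype=np.float64)
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))


def read_nifti(path, nucleus: str = "na") -> ImageVolume:
    """Read a NIfTI volume written by :func:`write_nifti`."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    try:
        nii = nib.load(str(p))
        data = np.asanyarray(nii.dataobj)
        affine = nii.affine
    except Exception as exc:  # nibabel raises various format errors
        raise ValueError(f"could not read NIfTI file {p}: {exc}") from exc
    voxel_size = tuple(float(v) for v in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(v) for v in affine[:3, 3])
    if data.ndim == 4 and data.shape[3] == 2:  # magnitude/phase pair
        vol = data[..., 0] * np.exp(1j * data[..., 1])
    else:
        vol = data
    geom = GridGeometry(vol.shape[:3], voxel_size, origin)
    return ImageVolume(geom, vol, nucleus, {"path": str(p)})


def save_kspace(path, samples: np.ndarray, coords: np.ndarray, dcf: np.ndarray,
                **meta) -> None:
    np.savez(path, samples=samples, coords=coords, dcf=dcf,
             **{k: np.asarray(v) for k, v in meta.items()})


def load_kspace(path) -> dict:
    with np.load(path) as f:
        return {k: f[k] for k in f.files}


def compartments_to_yaml(compartments, path) -> None:
    payload = [
        {
            "name": c.name,
            "center": list(c.center),
            "semi_axes": list(c.semi_axes),
            "concentration": c.concentration,
            "t1": c.t1,
            "t2star": c.t2star,
            "proton_density": c.proton_density,
        }
        for c in compartments
    ]
    Path(path).write_text(yaml.safe_dump(payload))


def compartments_from_yaml(path) -> list[CompartmentSpec]:
    payload = yaml.safe_load(Path(path).read_text())
    return [
        CompartmentSpec(
            c["name"], tuple(c["center"]), tuple(c["semi_axes"]),
            c["concentration"], c["t1"], c["t2star"],
            c.get("proton_density", 1.0),
        )
        for c in payload
    ]


def complex_to_pairs(arr: np.ndarray) -> list:
    """Serialize a complex array as nested [re, im] pairs for YAML/JSON."""
    stacked = np.stack([np.real(arr), np.imag(arr)], axis=-1)
    return stacked.tolist()


def pairs_to_complex(pairs) -> np.ndarray:
    arr = np.asarray(pairs, dtype=float)
    return arr[..., 0] + 1j * arr[..., 1]
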