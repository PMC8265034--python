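"""NIfTI and sidecar I/O.

All volumes are written as NIfTI with a diagonal affine carrying the voxel
size in mm; quantitative maps as 32-bit float, masks as unsigned 8-bit.
Phantoms are stored as one file per map plus a YAML sidecar with the seed
and configuration (units: mm for distances, ms for relaxation times).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .phantom import PhantomConfig, PhantomVolume
from .schedule import FingerprintSchedule
from .signal import BaselineStack

__all__ = [
    "read_nifti",
    "write_nifti",
    "read_stack",
    "write_stack",
    "save_phantom",
    "load_phantom",
]


def write_nifti(volume: np.ndarray, voxel_size, path, dtype=None) -> None:
    """Write a volume with a diagonal affine from the voxel size (mm)."""
    data = np.asarray(volume)
    if dtype is not None:
        data = data.astype(dtype)
    elif data.dtype == bool:
        data = data.astype(np.uint8)
    elif data.dtype not in (np.uint8, np.float32):
        data = data.astype(np.float32)
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(voxel_size) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def read_nifti(path):
    """Read a NIfTI volume; returns (data, voxel_size)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms)


def write_stack(stack: BaselineStack, path) -> None:
    write_nifti(stack.data, stack.voxel_size, path, dtype=np.float32)


def read_stack(path, schedule: FingerprintSchedule) -> BaselineStack:
    data, voxel_size = read_nifti(path)
    return BaselineStack(data=data, voxel_size=voxel_size, schedule=schedule)


_PHANTOM_MAPS = (
    ("t1_map", np.float32),
    ("t2s_map", np.float32),
    ("m0_map", np.float32),
    ("b1_map", np.float32),
    ("prob_nawm", np.float32),
    ("prob_gm", np.float32),
    ("prob_csf", np.float32),
    ("lesion_mask", np.uint8),
    ("brain_mask", np.uint8),
)


def save_phantom(phantom: PhantomVolume, directory) -> None:
    """Write one NIfTI per map plus a YAML sidecar with seed and config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, dtype in _PHANTOM_MAPS:
        write_nifti(getattr(phantom, name), phantom.voxel_size,
                    directory / f"{name}.nii.gz", dtype=dtype)
    sidecar = {
        "seed": phantom.seed,
        "voxel_size_mm": list(phantom.voxel_size),
        "units": {"t1_map": "ms", "t2s_map": "ms", "m0_map": "a.u.",
                  "b1_map": "dimensionless", "probabilities": "fraction"},
        "config": _config_to_dict(phantom.config),
    }
    (directory / "phantom.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))


def load_phantom(directory) -> PhantomVolume:
    directory = Path(directory)
    sidecar = yaml.safe_load((directory / "phantom.yaml").read_text())
    maps = {}
    for name, _ in _PHANTOM_MAPS:
        data, voxel_size = read_nifti(directory / f"{name}.nii.gz")
        maps[name] = data.astype(bool) if name.endswith("mask") else data
    config = _config_from_dict(sidecar["config"])
    return PhantomVolume(
        voxel_size=tuple(sidecar["voxel_size_mm"]),
        seed=int(sidecar["seed"]),
        config=config,
        **maps,
    )


def _config_to_dict(config: PhantomConfig) -> dict:
    d = dataclasses.asdict(config)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def _config_from_dict(d: dict) -> PhantomConfig:
    fields = {f.name: f for f in dataclasses.fields(PhantomConfig)}
    kwargs = {}
    for k, v in d.items():
        if k in fields:
            kwargs[k] = tuple(v) if isinstance(v, list) else v
    return PhantomConfig(**kwargs)
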