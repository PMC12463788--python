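"""Volume and projection-set serialization (NIfTI / HDF5 / JSON sidecars)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .acquisition import ProjectionSet
from .physics import SystemGeometry
from .reconstruction import ReconVolume


def save_volume(path: str | Path, volume: np.ndarray, voxel_mm: float) -> None:
    """Write a volume as NIfTI with isotropic voxel size in the header."""
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine),
             str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    voxel = float(img.header.get_zooms()[0])
    return np.asarray(img.dataobj, dtype=np.float64), voxel


def save_recon(path: str | Path, recon: ReconVolume) -> None:
    """Reconstruction as NIfTI plus a JSON sidecar with provenance."""
    path = Path(path)
    save_volume(path, recon.image, recon.voxel_mm)
    sidecar = path.with_suffix("").with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump({"n_iterations": recon.n_iterations,
                   "provenance": recon.provenance}, fh, indent=2, default=str)


def save_projections(path: str | Path, proj: ProjectionSet) -> None:
    """ProjectionSet as HDF5: one dataset per window, metadata as attrs."""
    with h5py.File(path, "w") as f:
        for w, arr in proj.windows.items():
            f.create_dataset(f"windows/{w}", data=arr, compression="gzip")
        f.attrs["duration_s"] = proj.duration_s
        f.attrs["collimator"] = proj.collimator
        f.attrs["isotope"] = proj.isotope
        f.attrs["n_angles"] = proj.geometry.n_angles
        f.attrs["rotation_radius_mm"] = proj.geometry.rotation_radius_mm
        f.attrs["grid_shape"] = proj.geometry.grid_shape
        f.attrs["voxel_mm"] = proj.geometry.voxel_mm
        f.attrs["provenance"] = json.dumps(proj.provenance, default=str)


def load_projections(path: str | Path) -> ProjectionSet:
    with h5py.File(path, "r") as f:
        windows = {w: f[f"windows/{w}"][()] for w in f["windows"]}
        geometry = SystemGeometry(
            n_angles=int(f.attrs["n_angles"]),
            rotation_radius_mm=float(f.attrs["rotation_radius_mm"]),
            grid_shape=int(f.attrs["grid_shape"]),
            voxel_mm=float(f.attrs["voxel_mm"]))
        return ProjectionSet(
            windows=windows, duration_s=float(f.attrs["duration_s"]),
            collimator=str(f.attrs["collimator"]),
            isotope=str(f.attrs["isotope"]), geometry=geometry,
            provenance=json.loads(f.attrs["provenance"]))
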