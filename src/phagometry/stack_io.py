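"""Reading and writing volumetric stacks and label maps.

Intensity stacks travel as multi-page TIFF (8/16-bit unsigned, ImageJ
metadata carries the voxel size) and label maps as NIfTI-1, which keeps
them editable in ITK-SNAP.  Either format is accepted for either role.
NIfTI stores data in (x, y, z) order on disk; everything is reordered to
the package-wide (z, y, x) convention at load time.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .volumes import IntensityVolume, LabelVolume, StackGeometry

log = logging.getLogger(__name__)

__all__ = [
    "read_stack",
    "write_stack",
    "read_labels",
    "write_labels",
    "sidecar_path",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in _NIFTI_SUFFIXES)


def _read_tiff(path: Path) -> tuple[np.ndarray, tuple[float, float, float] | None]:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        voxel = None
        # ImageJ convention: 'spacing' is the z step, page resolution is
        # pixels per unit in x/y.
        meta = tf.imagej_metadata or {}
        page = tf.pages[0]
        try:
            xres = page.tags["XResolution"].value
            yres = page.tags["YResolution"].value
            vx = xres[1] / xres[0]
            vy = yres[1] / yres[0]
            vz = float(meta.get("spacing", 0.0))
            if vx > 0 and vy > 0 and vz > 0:
                voxel = (vz, vy, vx)
        except (KeyError, ZeroDivisionError):
            voxel = None
    return data, voxel


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]  # (x, y, z)
    voxel = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return np.ascontiguousarray(data.T), voxel  # -> (z, y, x)


def read_stack(path, geometry_override: StackGeometry | None = None) -> IntensityVolume:
    """Read an intensity stack from TIFF or NIfTI.

    Geometry comes from file metadata; ``geometry_override`` replaces it
    (required for TIFFs without ImageJ voxel-size metadata, and the
    escape hatch for misdeclared headers).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    if _is_nifti(path):
        data, voxel = _read_nifti(path)
    else:
        data, voxel = _read_tiff(path)
    if data.ndim == 2:
        raise ValueError(f"{path}: single 2D page, a volumetric stack is required")
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D data, got ndim={data.ndim}")
    if not np.issubdtype(data.dtype, np.integer):
        raise TypeError(
            f"{path}: non-integer dtype {data.dtype}; intensity stacks must be integer"
        )
    if geometry_override is not None:
        if tuple(geometry_override.shape) != tuple(data.shape):
            raise ValueError(
                f"{path}: override shape {geometry_override.shape} does not match "
                f"file shape {tuple(data.shape)}"
            )
        geometry = geometry_override
    elif voxel is not None:
        geometry = StackGeometry(voxel_size_um=voxel, shape=tuple(data.shape))
    else:
        raise ValueError(
            f"{path}: no voxel-size metadata in file; pass geometry_override"
        )
    return IntensityVolume(values=data, geometry=geometry)


def write_stack(volume: IntensityVolume, path) -> Path:
    """Write an intensity stack; TIFF gets ImageJ voxel-size metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vz, vy, vx = volume.geometry.voxel_size_um
    if _is_nifti(path):
        _write_nifti_array(volume.values, volume.geometry, path)
    else:
        tifffile.imwrite(
            path,
            volume.values,
            imagej=True,
            resolution=(1.0 / vx, 1.0 / vy),
            metadata={"spacing": vz, "unit": "um", "axes": "ZYX"},
        )
    return path


def _write_nifti_array(values: np.ndarray, geometry: StackGeometry, path: Path) -> None:
    vz, vy, vx = geometry.voxel_size_um
    if values.dtype.itemsize > 4:  # NIfTI-1 has no 64-bit integer types
        if values.size and (values.min() < np.iinfo(np.int32).min or values.max() > np.iinfo(np.int32).max):
            raise ValueError("integer values exceed the int32 range supported by NIfTI-1")
        values = values.astype(np.int32)
    affine = np.diag([vx, vy, vz, 1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(values.T), affine)
    img.header.set_zooms((vx, vy, vz))
    nib.save(img, str(path))


def sidecar_path(path) -> Path:
    """Label-description sidecar for a label map: ``<stem>.labels.txt``."""
    path = Path(path)
    name = path.name
    for s in (".nii.gz", ".nii", ".tif", ".tiff"):
        if name.lower().endswith(s):
            name = name[: -len(s)]
            break
    return path.with_name(name + ".labels.txt")


def _read_sidecar(path: Path) -> dict[int, str]:
    names: dict[int, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        idx_str, _, name = line.partition("\t")
        if not name:
            raise ValueError(f"{path}: malformed sidecar line {line!r} (expected 'index<TAB>name')")
        names[int(idx_str)] = name.strip()
    return names


def read_labels(path, geometry: StackGeometry) -> LabelVolume:
    """Read a label map, attaching names from a sidecar when present.

    Missing sidecar entries are synthesized as ``label_<k>``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    if _is_nifti(path):
        data, _ = _read_nifti(path)
    else:
        data, _ = _read_tiff(path)
    if not np.issubdtype(data.dtype, np.integer):
        raise TypeError(f"{path}: label maps must be integer-valued, got dtype {data.dtype}")
    if tuple(data.shape) != tuple(geometry.shape):
        raise ValueError(
            f"{path}: label shape {tuple(data.shape)} does not match geometry shape "
            f"{geometry.shape}"
        )
    side = sidecar_path(path)
    names = _read_sidecar(side) if side.exists() else {}
    return LabelVolume.from_array(data, geometry, label_names=names)


def write_labels(labels: LabelVolume, path) -> Path:
    """Write a label map (NIfTI or TIFF) plus its name sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        _write_nifti_array(labels.labels, labels.geometry, path)
    else:
        vz, vy, vx = labels.geometry.voxel_size_um
        tifffile.imwrite(
            path,
            labels.labels,
            resolution=(1.0 / vx, 1.0 / vy),
        )
    if labels.label_names:
        lines = [f"{idx}\t{name}" for idx, name in sorted(labels.label_names.items())]
        sidecar_path(path).write_text("\n".join(lines) + "\n")
    return path
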