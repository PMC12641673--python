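"""Core in-memory containers for volumetric image stacks.

Axis order is ``(z, y, x)`` with 0-based indices throughout the package.
The voxel with index ``(i, j, k)`` occupies the physical box
``[i*sz, (i+1)*sz) x [j*sy, (j+1)*sy) x [k*sx, (k+1)*sx)`` in micrometres
and its *center* sits at ``((i+0.5)*sz, (j+0.5)*sy, (k+0.5)*sx)``.  All
rasterization in the package follows the voxel-center rule: a voxel
belongs to a continuous shape iff its center does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StackGeometry",
    "IntensityVolume",
    "LabelVolume",
    "MaskedChannel",
]


@dataclass(frozen=True)
class StackGeometry:
    """Per-axis voxel size (µm) and stack shape, both in (z, y, x) order.

    Voxel sizes may be anisotropic; every physical quantity in the
    package is computed with the per-axis sizes.
    """

    voxel_size_um: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        vs = tuple(float(v) for v in self.voxel_size_um)
        sh = tuple(int(s) for s in self.shape)
        if len(vs) != 3 or len(sh) != 3:
            raise ValueError("voxel_size_um and shape must each have 3 entries (z, y, x)")
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be > 0, got {vs}")
        if any(s < 1 for s in sh):
            raise ValueError(f"shape entries must be >= 1, got {sh}")
        object.__setattr__(self, "voxel_size_um", vs)
        object.__setattr__(self, "shape", sh)

    @property
    def voxel_volume_um3(self) -> float:
        vz, vy, vx = self.voxel_size_um
        return vz * vy * vx

    def voxels_to_um3(self, count: int | float) -> float:
        """Physical volume of ``count`` voxels, in µm³ (exact product)."""
        return count * self.voxel_volume_um3

    def voxel_centers_um(self, indices: np.ndarray) -> np.ndarray:
        """Physical centers (µm) of voxel indices, shape (n, 3) -> (n, 3)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return (idx + 0.5) * np.asarray(self.voxel_size_um)

    def um_to_voxel(self, point_um) -> np.ndarray:
        """Index of the voxel containing a physical point (floor rule)."""
        p = np.asarray(point_um, dtype=float)
        return np.floor(p / np.asarray(self.voxel_size_um)).astype(int)


def _check_3d(values: np.ndarray, geometry: StackGeometry, what: str) -> None:
    if values.ndim != 3:
        raise ValueError(f"{what} must be a 3D array, got ndim={values.ndim}")
    if tuple(values.shape) != geometry.shape:
        raise ValueError(
            f"{what} shape {tuple(values.shape)} does not match geometry shape {geometry.shape}"
        )


@dataclass
class IntensityVolume:
    """A single-channel stack of non-negative integer intensities."""

    values: np.ndarray
    geometry: StackGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise TypeError(
                f"intensity volumes must have an integer dtype, got {self.values.dtype}"
            )
        _check_3d(self.values, self.geometry, "intensity volume")
        if self.values.size and self.values.min() < 0:
            raise ValueError("intensity volumes must be non-negative")


@dataclass
class LabelVolume:
    """Integer-labeled 3D volume (0 = background) with named labels.

    Used for anatomical ROIs, rater segmentations and per-cell labels
    alike.  Every nonzero label present in ``labels`` must have an entry
    in ``label_names``.
    """

    labels: np.ndarray
    geometry: StackGeometry
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError(f"label volumes must have an integer dtype, got {self.labels.dtype}")
        _check_3d(self.labels, self.geometry, "label volume")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        present = self.present_labels()
        missing = [int(v) for v in present if int(v) not in self.label_names]
        if missing:
            raise ValueError(f"labels {missing} present in volume but absent from label_names")

    @classmethod
    def from_array(
        cls,
        labels: np.ndarray,
        geometry: StackGeometry,
        label_names: dict[int, str] | None = None,
        name_prefix: str = "label",
    ) -> "LabelVolume":
        """Build a LabelVolume, synthesizing ``<prefix>_<k>`` names if needed."""
        labels = np.asarray(labels)
        names = dict(label_names or {})
        for v in np.unique(labels):
            v = int(v)
            if v != 0 and v not in names:
                names[v] = f"{name_prefix}_{v}"
        return cls(labels=labels, geometry=geometry, label_names=names)

    def present_labels(self) -> list[int]:
        u = np.unique(self.labels)
        return [int(v) for v in u if v != 0]

    @property
    def name_to_label(self) -> dict[str, int]:
        return {name: idx for idx, name in self.label_names.items()}

    def mask_for(self, name: str) -> np.ndarray:
        """Binary support of one named label."""
        mapping = self.name_to_label
        if name not in mapping:
            raise KeyError(
                f"unknown label name {name!r}; available: {sorted(mapping)}"
            )
        return self.labels == mapping[name]


@dataclass
class MaskedChannel:
    """A marker channel restricted to a (dilated) ROI.

    ``values`` holds the original intensities inside the mask and 0
    outside; ``mask`` is the dilated ROI support itself, needed because
    genuinely-zero in-mask voxels must still enter threshold histograms.
    """

    values: IntensityVolume
    mask: np.ndarray
    roi_name: str = ""
    dilation_um: float = 0.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        _check_3d(self.mask, self.values.geometry, "mask")
        if self.dilation_um < 0:
            raise ValueError("dilation_um must be >= 0")
        if np.any(self.values.values[~self.mask]):
            raise ValueError("masked channel has nonzero intensities outside the mask")

    @property
    def geometry(self) -> StackGeometry:
        return self.values.geometry
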