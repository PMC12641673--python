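"""Macrophage segmentation from a masked marker channel.

The pipeline is: threshold the in-mask intensities (Otsu by default,
over in-mask voxels only, since the masked-out zeros would otherwise
dominate the histogram), label connected components at 26 connectivity,
drop small objects (strictly fewer than ``min_object_voxels`` voxels),
then drop upper-tail volume outliers (segmentation artifacts) with a
median + k * scaled-MAD rule.  Filters run in that order, so the
outlier statistic is computed on the size-filtered population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .config import SegmentationParams
from .volumes import LabelVolume, MaskedChannel

log = logging.getLogger(__name__)

__all__ = [
    "EmptyMaskError",
    "CellLabelResult",
    "threshold_channel",
    "label_components",
    "filter_small",
    "filter_outliers",
    "segment_cells",
]

_MAD_SCALE = 1.4826  # consistency factor for a normal distribution


class EmptyMaskError(ValueError):
    """Masked channel contains no usable voxels."""


@dataclass
class CellLabelResult:
    """Outcome of segmentation: compact cell labels 1..M plus bookkeeping."""

    cell_labels: LabelVolume
    removed_small: int
    removed_outliers: int
    threshold_used: float

    @property
    def n_cells(self) -> int:
        return len(self.cell_labels.present_labels())


def threshold_channel(masked: MaskedChannel, params: SegmentationParams) -> tuple[np.ndarray, float]:
    """Binarize a masked channel; returns (foreground, threshold used).

    Otsu is computed over in-mask voxels only and foreground is strictly
    above the threshold; a fixed threshold keeps voxels at or above it.
    """
    values = masked.values.values
    in_mask = masked.mask
    if not in_mask.any() or not np.any(values[in_mask]):
        raise EmptyMaskError("empty mask: no nonzero in-mask voxels to threshold")
    if params.threshold_method == "fixed":
        thresh = float(params.fixed_threshold)
        binary = (values >= thresh) & in_mask
    else:
        sample = values[in_mask]
        thresh = float(threshold_otsu(sample))
        binary = (values > thresh) & in_mask
    return binary, thresh


_STRUCTURES = {
    6: ndi.generate_binary_structure(3, 1),
    18: ndi.generate_binary_structure(3, 2),
    26: ndi.generate_binary_structure(3, 3),
}


def label_components(
    binary: np.ndarray,
    connectivity: int = 26,
    geometry=None,
    name_prefix: str = "cell",
) -> LabelVolume:
    """Connected-component labeling with deterministic label order.

    Labels are assigned by the raster-scan order of each component's
    first voxel, so the result is reproducible across runs.
    """
    binary = np.asarray(binary, dtype=bool)
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}, got {connectivity}")
    labeled, n = ndi.label(binary, structure=_STRUCTURES[connectivity])
    labeled = _relabel_scan_order(labeled, n)
    if geometry is None:
        from .volumes import StackGeometry

        geometry = StackGeometry(voxel_size_um=(1.0, 1.0, 1.0), shape=binary.shape)
    names = {i: f"{name_prefix}_{i:04d}" for i in range(1, int(labeled.max()) + 1)}
    return LabelVolume(labels=labeled, geometry=geometry, label_names=names)


def _relabel_scan_order(labeled: np.ndarray, n: int) -> np.ndarray:
    if n == 0:
        return labeled.astype(np.int32)
    flat = labeled.ravel()
    nz = np.flatnonzero(flat)
    _, first_pos = np.unique(flat[nz], return_index=True)
    order = np.argsort(nz[first_pos])  # old labels 1..n sorted by first voxel
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1 + order] = np.arange(1, n + 1, dtype=np.int32)
    return remap[labeled]


def _counts(labels: np.ndarray) -> np.ndarray:
    """Voxel counts per label, index 0 = background."""
    return np.bincount(labels.ravel())


def _keep_labels(cells: LabelVolume, keep: np.ndarray) -> LabelVolume:
    """Drop labels not in ``keep`` and recompact to 1..M, preserving order."""
    old = cells.labels
    max_label = int(old.max()) if old.size else 0
    remap = np.zeros(max_label + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1, dtype=np.int32)
    new_labels = remap[old]
    names = {}
    for new, old_label in enumerate(keep, start=1):
        names[new] = cells.label_names.get(int(old_label), f"cell_{new:04d}")
    return LabelVolume(labels=new_labels, geometry=cells.geometry, label_names=names)


def filter_small(cells: LabelVolume, min_object_voxels: int) -> tuple[LabelVolume, int]:
    """Remove objects with strictly fewer than ``min_object_voxels`` voxels."""
    counts = _counts(cells.labels)
    if len(counts) <= 1:
        return cells, 0
    labels = np.arange(1, len(counts))
    keep = labels[counts[1:] >= min_object_voxels]
    removed = len(labels) - len(keep) - int((counts[1:] == 0).sum())
    return _keep_labels(cells, keep), removed


def filter_outliers(
    cells: LabelVolume,
    rule: str = "upper_mad",
    mad_multiplier: float = 3.0,
) -> tuple[LabelVolume, int]:
    """Remove upper-tail volume outliers (segmentation artifacts).

    Under ``upper_mad``, objects whose voxel count exceeds
    ``median + mad_multiplier * 1.4826 * MAD`` are removed; only the
    upper tail is touched because the artifacts of interest are
    oversized merges.  Fewer than 3 objects, or MAD 0 (all volumes
    equal), is a no-op with a warning.
    """
    if rule == "none":
        return cells, 0
    if rule != "upper_mad":
        raise ValueError(f"unknown outlier rule {rule!r}")
    counts = _counts(cells.labels)
    labels = np.arange(1, len(counts))
    labels = labels[counts[1:] > 0]
    volumes = counts[labels].astype(float)
    if len(volumes) < 3:
        log.warning("outlier removal skipped: only %d objects (need >= 3)", len(volumes))
        return cells, 0
    median = float(np.median(volumes))
    mad = float(np.median(np.abs(volumes - median)))
    if mad == 0.0:
        log.warning("outlier removal skipped: MAD is 0 (all object volumes equal)")
        return cells, 0
    cutoff = median + mad_multiplier * _MAD_SCALE * mad
    keep = labels[volumes <= cutoff]
    removed = len(labels) - len(keep)
    if removed == 0:
        return cells, 0
    return _keep_labels(cells, keep), removed


def segment_cells(masked: MaskedChannel, params: SegmentationParams) -> CellLabelResult:
    """Full segmentation of one masked channel: threshold, label, filter."""
    binary, thresh = threshold_channel(masked, params)
    cells = label_components(binary, params.connectivity, masked.geometry)
    min_vox = params.min_object_voxels
    if params.min_object_um3 is not None:
        min_vox = int(np.ceil(params.min_object_um3 / masked.geometry.voxel_volume_um3))
    cells, removed_small = filter_small(cells, min_vox)
    cells, removed_outliers = filter_outliers(cells, params.outlier_rule, params.mad_multiplier)
    return CellLabelResult(
        cell_labels=cells,
        removed_small=removed_small,
        removed_outliers=removed_outliers,
        threshold_used=thresh,
    )
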