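"""Per-cell morphometrics, morphology classification and summaries.

The central measure is solidity, the ratio Vm/Vh of a cell's volume to
the volume of its convex hull (the smallest convex polyhedron
containing the whole cell).  Both volumes are taken in voxel space by
default: Vm is the object's voxel count and Vh is the number of voxel
centers inside or on the convex hull of the object's voxel centers
(rasterized hull).  This makes solidity exactly 1 for convex digital
shapes — filled cuboids, digital balls, straight lines — and bounds it
in (0, 1] for everything else.  Low solidity indicates a ramified
(branched) cell, high solidity an ameboid (compact) one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError

from .volumes import LabelVolume, StackGeometry

log = logging.getLogger(__name__)

__all__ = [
    "CellMorphometry",
    "cell_volume",
    "hull_solidity",
    "equiv_radius",
    "classify_morphology",
    "assign_region",
    "occupancy",
    "measure_cells",
    "summarize",
]

UNASSIGNED = "unassigned"
_HULL_TOL = 1e-9


@dataclass
class CellMorphometry:
    """Morphometrics of one segmented object."""

    cell_id: int
    voxel_count: int
    volume_um3: float
    hull_voxels: int
    hull_volume_um3: float
    solidity: float
    equiv_radius_um: float
    centroid_um: tuple[float, float, float]
    region: str = UNASSIGNED
    morphology: str = ""


def cell_volume(voxel_count: int, geometry: StackGeometry) -> float:
    """Physical volume in µm³: voxel count scaled by the voxel volume."""
    if voxel_count < 1:
        raise ValueError(f"an object needs at least 1 voxel, got {voxel_count}")
    return geometry.voxels_to_um3(voxel_count)


def _rasterized_hull_count(points: np.ndarray) -> int:
    """Voxel centers inside or on the hull of integer points.

    Degenerate inputs (fewer than 4 points, or all points collinear /
    coplanar) get the documented convention: the hull rasterizes to the
    point set itself.
    """
    n = len(points)
    if n <= 3:
        return n
    try:
        hull = ConvexHull(points.astype(float))
    except QhullError:
        return n
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    grids = np.meshgrid(*[np.arange(lo[i], hi[i] + 1) for i in range(3)], indexing="ij")
    cand = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    normals = hull.equations[:, :3]
    offsets = hull.equations[:, 3]
    inside = np.all(cand @ normals.T + offsets <= _HULL_TOL, axis=1)
    return int(np.count_nonzero(inside))


def _continuous_hull_volume_um3(points: np.ndarray, geometry: StackGeometry) -> float:
    """Volume (µm³) of the hull of the voxels' physical *corner* points.

    Using the 8 corners of each voxel cube (not the centers) makes the
    continuous hull of a filled cuboid equal its true physical volume.
    """
    vs = np.asarray(geometry.voxel_size_um)
    corners = []
    for dz in (0.0, 1.0):
        for dy in (0.0, 1.0):
            for dx in (0.0, 1.0):
                corners.append((points + np.array([dz, dy, dx])) * vs)
    allpts = np.concatenate(corners, axis=0)
    return float(ConvexHull(allpts).volume)


def hull_solidity(
    voxels: np.ndarray,
    geometry: StackGeometry | None = None,
    hull_mode: str = "rasterized",
) -> tuple[float, float]:
    """Hull volume and solidity Vm/Vh of a voxel set.

    Parameters
    ----------
    voxels : (n, 3) integer array of voxel indices.
    hull_mode : "rasterized" (default) counts voxel centers inside the
        hull polytope; "continuous" uses the physical polytope volume of
        the voxel corner points (requires ``geometry``).

    Returns ``(hull_voxels_or_volume, solidity)``; in rasterized mode
    the first element is the hull voxel count.
    """
    voxels = np.asarray(voxels, dtype=int)
    if voxels.ndim != 2 or voxels.shape[1] != 3 or len(voxels) == 0:
        raise ValueError("voxels must be a non-empty (n, 3) index array")
    vm = len(voxels)
    if hull_mode == "rasterized":
        vh = _rasterized_hull_count(voxels)
        return vh, vm / vh
    if hull_mode == "continuous":
        if geometry is None:
            raise ValueError("continuous hull mode requires a geometry")
        try:
            vh_um3 = _continuous_hull_volume_um3(voxels, geometry)
        except QhullError:  # degenerate even with corners; fall back
            vh_um3 = geometry.voxels_to_um3(vm)
        vm_um3 = geometry.voxels_to_um3(vm)
        return vh_um3, min(vm_um3 / vh_um3, 1.0)
    raise ValueError(f"unknown hull_mode {hull_mode!r}")


def equiv_radius(volume_um3: float) -> float:
    """Equivalent-sphere radius (µm) of a volume: (3V / 4π)^(1/3)."""
    if volume_um3 <= 0:
        raise ValueError(f"volume must be > 0, got {volume_um3}")
    return (3.0 * volume_um3 / (4.0 * math.pi)) ** (1.0 / 3.0)


def classify_morphology(solidity: float, threshold: float = 0.5) -> str:
    """"ramified" iff solidity < threshold, else "ameboid" (>= rule)."""
    if not 0.0 < solidity <= 1.0:
        raise ValueError(f"solidity must lie in (0, 1], got {solidity}")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie strictly between 0 and 1, got {threshold}")
    return "ramified" if solidity < threshold else "ameboid"


def _region_distance_maps(roi_labels: LabelVolume) -> dict[str, np.ndarray]:
    """Per-region physical distance (µm) from every voxel center to the
    nearest ROI voxel center."""
    maps = {}
    sampling = roi_labels.geometry.voxel_size_um
    for name, idx in sorted(roi_labels.name_to_label.items()):
        mask = roi_labels.labels == idx
        if not mask.any():
            continue
        maps[name] = ndi.distance_transform_edt(~mask, sampling=sampling)
    return maps


def assign_region(
    voxels: np.ndarray,
    roi_labels: LabelVolume,
    max_distance_um: float,
    _distance_maps: dict[str, np.ndarray] | None = None,
) -> str:
    """Nearest-ROI assignment of a cell.

    Distance is the physical center-to-center distance from any cell
    voxel to the nearest voxel of each ROI; the closest ROI wins, ties
    break lexicographically on the region name, and a cell farther than
    ``max_distance_um`` from every ROI is "unassigned".
    """
    voxels = np.asarray(voxels, dtype=int)
    maps = _distance_maps if _distance_maps is not None else _region_distance_maps(roi_labels)
    if not maps:
        log.warning("ROI map has no labeled regions; all cells unassigned")
        return UNASSIGNED
    best_name = UNASSIGNED
    best_dist = np.inf
    for name in sorted(maps):
        d = float(maps[name][voxels[:, 0], voxels[:, 1], voxels[:, 2]].min())
        if d < best_dist:  # strict: lexicographically-first name wins ties
            best_dist = d
            best_name = name
    if best_dist > max_distance_um + _HULL_TOL:
        return UNASSIGNED
    return best_name


def occupancy(cell_labels: LabelVolume | np.ndarray, roi_mask: np.ndarray, geometry=None) -> float:
    """Fraction of an ROI's voxels occupied by segmented cells."""
    labels = cell_labels.labels if isinstance(cell_labels, LabelVolume) else np.asarray(cell_labels)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if labels.shape != roi_mask.shape:
        raise ValueError(f"shape mismatch: cells {labels.shape} vs ROI {roi_mask.shape}")
    n_roi = int(np.count_nonzero(roi_mask))
    if n_roi == 0:
        raise ValueError("empty ROI: occupancy is undefined")
    n_cells = int(np.count_nonzero((labels > 0) & roi_mask))
    return n_cells / n_roi


def measure_cells(
    cell_labels: LabelVolume,
    roi_labels: LabelVolume | None = None,
    *,
    solidity_threshold: float = 0.5,
    max_distance_um: float = np.inf,
    hull_mode: str = "rasterized",
) -> pd.DataFrame:
    """Morphometrics table for every labeled object.

    Columns: cell_id, region, morphology, voxel_count, volume_um3,
    hull_voxels, hull_volume_um3, solidity, equiv_radius_um,
    centroid_z_um / _y_um / _x_um.
    """
    geometry = cell_labels.geometry
    vs = np.asarray(geometry.voxel_size_um)
    arr = cell_labels.labels
    dist_maps = _region_distance_maps(roi_labels) if roi_labels is not None else {}
    if roi_labels is not None and not dist_maps:
        log.warning("ROI map has no labeled regions; all cells unassigned")
    rows = []
    slices = ndi.find_objects(arr)
    for label, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        offset = np.array([s.start for s in sl])
        voxels = np.argwhere(arr[sl] == label) + offset
        count = len(voxels)
        vol = cell_volume(count, geometry)
        hull_val, solidity = hull_solidity(voxels, geometry, hull_mode=hull_mode)
        if hull_mode == "rasterized":
            hull_voxels = int(hull_val)
            hull_um3 = geometry.voxels_to_um3(hull_voxels)
        else:
            hull_voxels = count  # not meaningful in continuous mode
            hull_um3 = float(hull_val)
        centroid = tuple(((voxels + 0.5) * vs).mean(axis=0))
        region = (
            assign_region(voxels, roi_labels, max_distance_um, _distance_maps=dist_maps)
            if dist_maps
            else UNASSIGNED
        )
        rows.append(
            {
                "cell_id": label,
                "region": region,
                "morphology": classify_morphology(solidity, solidity_threshold),
                "voxel_count": count,
                "volume_um3": vol,
                "hull_voxels": hull_voxels,
                "hull_volume_um3": hull_um3,
                "solidity": solidity,
                "equiv_radius_um": equiv_radius(vol),
                "centroid_z_um": centroid[0],
                "centroid_y_um": centroid[1],
                "centroid_x_um": centroid[2],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id", "region", "morphology", "voxel_count", "volume_um3",
            "hull_voxels", "hull_volume_um3", "solidity", "equiv_radius_um",
            "centroid_z_um", "centroid_y_um", "centroid_x_um",
        ],
    )


_SUMMARY_COLUMNS = [
    "region", "n_cells",
    "solidity_mean", "solidity_sd",
    "volume_mean_um3", "volume_sd_um3",
    "radius_mean_um", "radius_sd_um",
    "sd_defined",
]


def _summary_row(region: str, sub: pd.DataFrame) -> dict:
    n = len(sub)
    row = {"region": region, "n_cells": n, "sd_defined": n > 1}
    for col, out in (
        ("solidity", "solidity"),
        ("volume_um3", "volume"),
        ("equiv_radius_um", "radius"),
    ):
        suffix = "_um3" if out == "volume" else ("_um" if out == "radius" else "")
        if n == 0:
            mean, sd = float("nan"), float("nan")
        else:
            mean = float(sub[col].mean())
            sd = float(sub[col].std(ddof=1)) if n > 1 else 0.0
        row[f"{out}_mean{suffix}"] = mean
        row[f"{out}_sd{suffix}"] = sd
    return row


def summarize(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-region summary table plus an "All" row aggregating every cell.

    Means use the sample standard deviation (n-1 denominator); a region
    with a single cell reports sd 0 with ``sd_defined`` False.  Counts
    satisfy: sum of region rows (unassigned included) equals "All".
    """
    if len(cells) == 0:
        return pd.DataFrame([_summary_row("All", cells)], columns=_SUMMARY_COLUMNS)
    rows = []
    regions = sorted(r for r in cells["region"].unique() if r != UNASSIGNED)
    if (cells["region"] == UNASSIGNED).any():
        regions.append(UNASSIGNED)
    for region in regions:
        rows.append(_summary_row(region, cells[cells["region"] == region]))
    rows.append(_summary_row("All", cells))
    return pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)
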