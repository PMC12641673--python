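"""Independent brute-force oracles used to validate the implementation.

These deliberately use different algorithms from the package code:
pure-Python flood fill, exact rational arithmetic, Delaunay-based point
membership, and all-pairs distance checks.
"""

from fractions import Fraction

import numpy as np
from scipy.spatial import Delaunay, QhullError


def lattice_ellipsoid_count(semi_axes_vox) -> int:
    """Integer lattice points (i, j, k) with sum((x/a)^2) <= 1, centered at 0."""
    a, b, c = semi_axes_vox
    n = 0
    for i in range(-int(a) - 1, int(a) + 2):
        for j in range(-int(b) - 1, int(b) + 2):
            for k in range(-int(c) - 1, int(c) + 2):
                if (i / a) ** 2 + (j / b) ** 2 + (k / c) ** 2 <= 1.0 + 1e-12:
                    n += 1
    return n


def hull_voxel_count(points: np.ndarray) -> int:
    """Voxel centers inside/on the convex hull, via Delaunay membership.

    Degenerate (rank-deficient) point sets follow the package-wide
    convention: the hull rasterizes to the point set itself.
    """
    points = np.asarray(points, dtype=float)
    if len(points) <= 3:
        return len(points)
    try:
        tri = Delaunay(points)
    except QhullError:
        return len(points)
    lo = points.min(axis=0).astype(int)
    hi = points.max(axis=0).astype(int)
    count = 0
    for i in range(lo[0], hi[0] + 1):
        for j in range(lo[1], hi[1] + 1):
            for k in range(lo[2], hi[2] + 1):
                if tri.find_simplex(np.array([i, j, k], dtype=float)) >= 0:
                    count += 1
    return count


def fleiss_kappa_exact(counts) -> Fraction:
    """Fleiss kappa in exact rational arithmetic."""
    rows = [[int(v) for v in row] for row in counts]
    N = len(rows)
    n = sum(rows[0])
    sum_sq = sum(v * v for row in rows for v in row)
    p0 = Fraction(sum_sq - N * n, N * n * (n - 1))
    col_sums = [sum(row[j] for row in rows) for j in range(len(rows[0]))]
    pe = sum((Fraction(s, N * n)) ** 2 for s in col_sums)
    if pe == 1:
        raise ZeroDivisionError("pe == 1")
    return (p0 - pe) / (1 - pe)


_NEIGHBORS = {
    6: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if abs(dz) + abs(dy) + abs(dx) == 1],
    26: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
         if (dz, dy, dx) != (0, 0, 0)],
}


def flood_fill_components(binary: np.ndarray, connectivity: int) -> list[set]:
    """Connected components as sets of voxel tuples, by BFS flood fill."""
    binary = np.asarray(binary, dtype=bool)
    remaining = set(map(tuple, np.argwhere(binary)))
    offsets = _NEIGHBORS[connectivity]
    components = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            z, y, x = frontier.pop()
            for dz, dy, dx in offsets:
                nb = (z + dz, y + dy, x + dx)
                if nb in remaining:
                    remaining.discard(nb)
                    comp.add(nb)
                    frontier.append(nb)
        components.append(comp)
    return components


def brute_force_dilation(mask: np.ndarray, radius_um: float, voxel_size_um) -> np.ndarray:
    """A voxel is dilated iff its center is within radius of some mask
    voxel center (per-axis physical scaling); checked all-pairs."""
    mask = np.asarray(mask, dtype=bool)
    vs = np.asarray(voxel_size_um, dtype=float)
    sources = np.argwhere(mask) * vs
    out = np.zeros_like(mask)
    if len(sources) == 0:
        return out
    for idx in np.ndindex(mask.shape):
        p = np.asarray(idx) * vs
        d2 = np.sum((sources - p) ** 2, axis=1)
        if d2.min() <= radius_um**2 + 1e-9:
            out[idx] = True
    return out
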