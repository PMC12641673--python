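"""Synthetic two-channel phantoms with exact ground truth.

The generator emulates the geometry this pipeline is built for: narrow
tubular ducts/vessels (reuniting duct, endolymphatic duct, associated
veins) embedded in background, each wearing a periductal cuff of
macrophages.  Two cell morphologies are produced: compact ellipsoidal
"ameboid" cells and thin branched "ramified" cells whose convex-hull
solidity is low by construction.  The marker channel carries the cells
over a constant background with optional additive Gaussian noise; the
structure channel renders the tube walls and is decorative —
segmentation consumes ROI label maps, not the structure signal.

All rasterization follows the voxel-center rule (a voxel belongs to a
shape iff its center is inside), matching the hull-rasterization
convention in :mod:`phagometry.morphometry`, so convex phantom shapes
have solidity exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial.transform import Rotation

from .volumes import IntensityVolume, LabelVolume, StackGeometry

log = logging.getLogger(__name__)

__all__ = [
    "TubeSpec",
    "PhantomConfig",
    "PhantomTruth",
    "PlacementError",
    "default_phantom_config",
    "generate_phantom",
    "rasterize_ameboid",
    "rasterize_ramified",
    "simulate_raters",
]


class PlacementError(RuntimeError):
    """Raised when a cell cannot be placed within the attempt budget."""


@dataclass
class TubeSpec:
    """One tubular ROI: a polyline centerline (µm, z/y/x) and a radius."""

    name: str
    points_um: list[tuple[float, float, float]]
    radius_um: float

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError(f"tube radius must be > 0, got {self.radius_um}")
        self.points_um = [tuple(float(c) for c in p) for p in self.points_um]
        if len(self.points_um) < 2:
            raise ValueError("a tube centerline needs at least 2 control points")


def _default_regions() -> list[TubeSpec]:
    # Two parallel ducts along y, far enough apart that their cuffs and
    # dilated masks cannot claim each other's cells.
    return [
        TubeSpec("ed", [(80.0, 0.0, 64.0), (80.0, 320.0, 64.0)], 10.0),
        TubeSpec("vva", [(80.0, 0.0, 192.0), (80.0, 320.0, 192.0)], 10.0),
    ]


def _default_cells() -> dict[str, tuple[int, int]]:
    return {"ed": (10, 10), "vva": (10, 10)}


@dataclass
class PhantomConfig:
    """Phantom study conditions.

    Defaults describe the scenario the test-bed exercises end to end:
    a 160x320x256 µm block at 2 µm isotropic voxels holding two
    parallel 10 µm radius ducts, each cuffed by 10 ameboid and 10
    ramified cells.
    Ameboid equivalent radii (``ameboid_axes_um``, 8-12 µm) bracket the
    radii of real periductal macrophages, with cell volume sampled
    uniformly between the bounding spheres.  Ramified cells get a 6 µm
    soma plus 4-7 thin branches grown step by step until the cell
    reaches a volume target drawn uniformly over the same band (branch
    thickness scales 2-4.5 µm with the target, lengths are capped at
    40 µm).  Both morphologies therefore share one volume distribution,
    as observed in tissue, while differing sharply in solidity.
    """

    shape: tuple[int, int, int] = (80, 160, 128)
    voxel_size_um: tuple[float, float, float] = (2.0, 2.0, 2.0)
    regions: list[TubeSpec] = field(default_factory=_default_regions)
    cells_per_region: dict[str, tuple[int, int]] = field(default_factory=_default_cells)
    ameboid_axes_um: tuple[float, float] = (8.0, 12.0)
    n_branches_range: tuple[int, int] = (5, 8)
    branch_len_um_range: tuple[float, float] = (20.0, 40.0)
    branch_thickness_um_range: tuple[float, float] = (2.5, 5.5)
    soma_radius_um: float = 6.0
    branch_wobble: float = 0.35
    shell_distance_um: float = 10.0
    min_cell_voxels: int = 110
    marker_intensity: int = 200
    background_intensity: int = 10
    structure_intensity: int = 120
    noise_sd: float = 0.0
    seed: int = 0
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        self.regions = [
            r if isinstance(r, TubeSpec) else TubeSpec(**r) for r in self.regions
        ]
        self.cells_per_region = {
            str(k): (int(v[0]), int(v[1])) for k, v in self.cells_per_region.items()
        }
        region_names = [r.name for r in self.regions]
        if len(set(region_names)) != len(region_names):
            raise ValueError("duplicate region names in phantom config")
        unknown = sorted(set(self.cells_per_region) - set(region_names))
        if unknown:
            raise ValueError(f"cells requested for unknown regions {unknown}")
        if any(n < 0 for pair in self.cells_per_region.values() for n in pair):
            raise ValueError("cell counts must be >= 0")
        if self.marker_intensity <= self.background_intensity:
            raise ValueError("marker_intensity must exceed background_intensity")
        if min(self.marker_intensity, self.background_intensity, self.structure_intensity) < 0:
            raise ValueError("intensities must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.shell_distance_um < 0:
            raise ValueError("shell_distance_um must be >= 0")

    @property
    def geometry(self) -> StackGeometry:
        return StackGeometry(voxel_size_um=self.voxel_size_um, shape=self.shape)


def default_phantom_config(seed: int = 0, noise_sd: float = 0.0) -> PhantomConfig:
    """The default study conditions with an explicit seed and noise level."""
    return PhantomConfig(seed=seed, noise_sd=noise_sd)


@dataclass
class PhantomTruth:
    """Exact ground truth: per-cell labels, ROI labels and truth tables."""

    cell_labels: LabelVolume
    roi_labels: LabelVolume
    per_cell: pd.DataFrame  # cell_id, region, morphology, voxel_count, solidity
    per_region: pd.DataFrame  # region, n_ameboid, n_ramified, n_total


# ---------------------------------------------------------------------------
# rasterizers


def _center_grids(geometry: StackGeometry):
    vz, vy, vx = geometry.voxel_size_um
    nz, ny, nx = geometry.shape
    cz = ((np.arange(nz) + 0.5) * vz)[:, None, None]
    cy = ((np.arange(ny) + 0.5) * vy)[None, :, None]
    cx = ((np.arange(nx) + 0.5) * vx)[None, None, :]
    return cz, cy, cx


def _tube_distance(geometry: StackGeometry, points_um) -> np.ndarray:
    """Exact distance (µm) from every voxel center to a polyline."""
    cz, cy, cx = _center_grids(geometry)
    dist2 = np.full(geometry.shape, np.inf)
    pts = np.asarray(points_um, dtype=float)
    for a, b in zip(pts[:-1], pts[1:]):
        d = b - a
        denom = float(d @ d)
        pz, py, px = cz - a[0], cy - a[1], cx - a[2]
        if denom == 0.0:
            q2 = pz**2 + py**2 + px**2
        else:
            t = np.clip((pz * d[0] + py * d[1] + px * d[2]) / denom, 0.0, 1.0)
            q2 = (pz - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (px - t * d[2]) ** 2
        np.minimum(dist2, q2, out=dist2)
    return np.sqrt(dist2)


_EPS = 1e-9


def rasterize_ameboid(
    center_um,
    semi_axes_um,
    orientation: np.ndarray,
    geometry: StackGeometry,
) -> np.ndarray:
    """Voxel indices (n, 3) whose centers lie inside a rotated ellipsoid.

    ``orientation`` is a 3x3 rotation matrix mapping body coordinates to
    world coordinates; ``semi_axes_um`` are the body-frame semi-axes.
    """
    center = np.asarray(center_um, dtype=float)
    axes = np.asarray(semi_axes_um, dtype=float)
    R = np.asarray(orientation, dtype=float)
    if axes.shape != (3,) or np.any(axes <= 0):
        raise ValueError(f"semi-axes must be 3 positive reals, got {axes}")
    vs = np.asarray(geometry.voxel_size_um)
    reach = float(axes.max())
    lo = np.maximum(np.floor((center - reach) / vs - 1), 0).astype(int)
    hi = np.minimum(np.ceil((center + reach) / vs + 1), geometry.shape).astype(int)
    if np.any(lo >= hi):
        raise ValueError("ellipsoid lies entirely outside the volume")
    grids = np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)], indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    centers = (idx + 0.5) * vs
    body = (centers - center) @ R  # R.T applied row-wise
    inside = np.sum((body / axes) ** 2, axis=1) <= 1.0 + _EPS
    voxels = idx[inside]
    if voxels.size == 0:
        raise ValueError("ellipsoid rasterized to an empty voxel set (too small for this grid)")
    return voxels


def _stamp_points(points_um: np.ndarray, radius_um: float, geometry, out: set) -> None:
    """Add every voxel whose center is within radius of any point.

    Each point always contributes at least its containing voxel, so a
    stamped path with sub-voxel step spacing is 26-connected even when
    the radius is below half a voxel.
    """
    vs = np.asarray(geometry.voxel_size_um)
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    hosts = np.floor(pts / vs).astype(int)
    offsets = _ball_offsets_cached(radius_um, tuple(geometry.voxel_size_um))
    cand = (hosts[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    centers = (cand + 0.5) * vs
    d2 = np.sum((centers - np.repeat(pts, len(offsets), axis=0)) ** 2, axis=1)
    keep = cand[d2 <= radius_um**2 + _EPS]
    for c in np.unique(np.concatenate([keep, hosts]), axis=0):
        out.add((int(c[0]), int(c[1]), int(c[2])))


_BALL_CACHE: dict[tuple, np.ndarray] = {}


def _ball_offsets_cached(radius_um: float, voxel_size: tuple) -> np.ndarray:
    key = (round(radius_um, 6), voxel_size)
    if key not in _BALL_CACHE:
        # widen by one voxel so sub-voxel point positions are covered
        vs = np.asarray(voxel_size, dtype=float)
        r = np.maximum(np.floor(radius_um / vs) + 1, 0).astype(int)
        grids = np.meshgrid(*[np.arange(-ri, ri + 1) for ri in r], indexing="ij")
        off = np.stack([g.ravel() for g in grids], axis=1)
        keep = np.sum((np.abs(off) - 1).clip(min=0) ** 2 * vs**2, axis=1) <= radius_um**2 + _EPS
        _BALL_CACHE[key] = off[keep]
    return _BALL_CACHE[key]


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ValueError("zero-length direction vector")
    return v / n


def rasterize_ramified(
    soma_center_um,
    n_branches: int,
    branch_len_um: float,
    thickness_um: float,
    rng: np.random.Generator,
    geometry: StackGeometry,
    *,
    soma_radius_um: float = 5.0,
    directions=None,
    wobble: float = 0.35,
    branch_lengths_um=None,
    target_voxels: int | None = None,
) -> np.ndarray:
    """Rasterize a ramified cell: a spherical soma plus branch tubes.

    Branches are random walks starting at the soma center; ``wobble``
    scales the per-step random turn (0 gives straight branches).  Step
    length is half the smallest voxel size, so the stamped path is
    26-connected by construction.  Explicit unit ``directions`` (one per
    branch) override the random isotropic draw; ``branch_lengths_um``
    overrides the common ``branch_len_um``.

    When ``target_voxels`` is given, branches grow round-robin until
    the cell reaches that voxel count (or every branch hits the
    ``branch_len_um`` length cap), which decouples a ramified cell's
    volume from its branch geometry.
    """
    if n_branches < 2:
        raise ValueError("a ramified cell needs at least 2 branches")
    if branch_lengths_um is None:
        branch_lengths_um = [branch_len_um] * n_branches
    branch_lengths_um = [float(L) for L in branch_lengths_um]
    if len(branch_lengths_um) != n_branches:
        raise ValueError("branch_lengths_um must have one entry per branch")
    if min(branch_lengths_um) <= 0:
        raise ValueError("branch length must be > 0")
    if thickness_um <= 0:
        raise ValueError("branch thickness must be > 0")
    center = np.asarray(soma_center_um, dtype=float)
    voxels: set[tuple[int, int, int]] = set()
    _stamp_points(center, soma_radius_um, geometry, voxels)
    if directions is not None:
        dirs = [_unit(np.asarray(d, dtype=float)) for d in directions]
        if len(dirs) != n_branches:
            raise ValueError("number of directions must equal n_branches")
    else:
        dirs = [_unit(rng.normal(size=3)) for _ in range(n_branches)]
    step = 0.5 * min(geometry.voxel_size_um)
    tube_r = thickness_um / 2.0
    chunk = 4  # steps stamped per batch; also the growth-check granularity

    def _advance(state) -> list[np.ndarray]:
        pts = []
        for _ in range(chunk):
            if state["traveled"] >= state["cap"] - _EPS:
                break
            s = min(step, state["cap"] - state["traveled"])
            state["p"] = state["p"] + s * state["d"]
            state["traveled"] += s
            pts.append(state["p"])
            if wobble > 0:
                state["d"] = _unit(state["d"] + wobble * (s / 5.0) * rng.normal(size=3))
        return pts

    states = [
        {"d": d0.copy(), "p": center.copy(), "traveled": 0.0, "cap": cap}
        for d0, cap in zip(dirs, branch_lengths_um)
    ]
    active = list(states)
    while active and (target_voxels is None or len(voxels) < target_voxels):
        for st in list(active):
            pts = _advance(st)
            if pts:
                _stamp_points(np.array(pts), tube_r, geometry, voxels)
            if st["traveled"] >= st["cap"] - _EPS:
                active.remove(st)
            if target_voxels is not None and len(voxels) >= target_voxels:
                break
    arr = np.array(sorted(voxels), dtype=int)
    shape = np.asarray(geometry.shape)
    if np.any(arr < 0) or np.any(arr >= shape):
        # caller decides whether out-of-bounds is a rejection; clip here
        # would silently distort morphology, so report instead
        raise ValueError("ramified cell extends outside the volume")
    return arr


# ---------------------------------------------------------------------------
# generation


def _dilate1_into(blocked: np.ndarray, voxels: np.ndarray) -> None:
    """Mark voxels and their full 26-neighborhood in ``blocked``."""
    shape = blocked.shape
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                v = voxels + np.array([dz, dy, dx])
                ok = np.all((v >= 0) & (v < np.asarray(shape)), axis=1)
                vv = v[ok]
                blocked[vv[:, 0], vv[:, 1], vv[:, 2]] = True


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def generate_phantom(
    config: PhantomConfig,
) -> tuple[IntensityVolume, IntensityVolume, PhantomTruth]:
    """Generate the two-channel phantom and its exact ground truth.

    Deterministic for a given config (the seed drives placement and
    noise through independent child streams).  Cells are placed by
    rejection sampling in a shell around their region's surface and are
    kept at least one voxel apart, so noise-free segmentation at 26
    connectivity recovers them one-to-one.
    """
    from . import morphometry  # local import; morphometry has no phantom dependency

    geometry = config.geometry
    ss = np.random.SeedSequence(config.seed)
    rng_place, rng_marker, rng_struct = (np.random.default_rng(s) for s in ss.spawn(3))

    # --- ROI label map
    roi_arr = np.zeros(geometry.shape, dtype=np.int16)
    roi_names: dict[int, str] = {}
    tube_dists: dict[str, np.ndarray] = {}
    for i, tube in enumerate(config.regions, start=1):
        dist = _tube_distance(geometry, tube.points_um)
        mask = dist <= tube.radius_um + _EPS
        if np.any(roi_arr[mask]):
            raise ValueError(f"tube {tube.name!r} overlaps another region")
        roi_arr[mask] = i
        roi_names[i] = tube.name
        tube_dists[tube.name] = dist
    roi_labels = LabelVolume(labels=roi_arr, geometry=geometry, label_names=roi_names)
    any_tube = roi_arr > 0

    # --- cell placement
    cell_arr = np.zeros(geometry.shape, dtype=np.int32)
    blocked = np.zeros(geometry.shape, dtype=bool)
    rows = []
    next_id = 1
    lo_ax, hi_ax = config.ameboid_axes_um
    for tube in config.regions:
        n_am, n_ram = config.cells_per_region.get(tube.name, (0, 0))
        if n_am + n_ram == 0:
            continue
        surf_dist = tube_dists[tube.name] - tube.radius_um
        shell = (~any_tube) & (surf_dist > 0) & (surf_dist <= config.shell_distance_um + _EPS)
        shell_idx = np.argwhere(shell)
        if shell_idx.size == 0:
            raise PlacementError(f"region {tube.name!r} has an empty placement shell")
        for morphology, count in (("ameboid", n_am), ("ramified", n_ram)):
            for _ in range(count):
                voxels = _place_one(
                    config, geometry, morphology, shell_idx, blocked, rng_place,
                    lo_ax, hi_ax,
                )
                if voxels is None:
                    raise PlacementError(
                        f"could not place a {morphology} cell near {tube.name!r} after "
                        f"{config.max_attempts} attempts; use a larger volume or fewer cells"
                    )
                cell_arr[voxels[:, 0], voxels[:, 1], voxels[:, 2]] = next_id
                _dilate1_into(blocked, voxels)
                _, solidity = morphometry.hull_solidity(voxels)
                rows.append(
                    {
                        "cell_id": next_id,
                        "region": tube.name,
                        "morphology": morphology,
                        "voxel_count": int(len(voxels)),
                        "solidity": solidity,
                    }
                )
                next_id += 1

    per_cell = pd.DataFrame(
        rows, columns=["cell_id", "region", "morphology", "voxel_count", "solidity"]
    )
    per_region = _per_region_counts(per_cell, [t.name for t in config.regions])
    cell_names = {int(r["cell_id"]): f"cell_{int(r['cell_id']):04d}" for r in rows}
    cell_labels = LabelVolume(labels=cell_arr, geometry=geometry, label_names=cell_names)

    # --- channels
    marker = _render_channel(
        base=np.where(cell_arr > 0, config.marker_intensity, config.background_intensity),
        noise_sd=config.noise_sd,
        rng=rng_marker,
        geometry=geometry,
    )
    wall_half = max(geometry.voxel_size_um)
    struct_base = np.full(geometry.shape, config.background_intensity, dtype=np.int64)
    for tube in config.regions:
        wall = np.abs(tube_dists[tube.name] - tube.radius_um) <= wall_half
        struct_base[wall] = config.structure_intensity
    structure = _render_channel(struct_base, config.noise_sd, rng_struct, geometry)

    truth = PhantomTruth(
        cell_labels=cell_labels, roi_labels=roi_labels, per_cell=per_cell, per_region=per_region
    )
    return structure, marker, truth


def _place_one(config, geometry, morphology, shell_idx, blocked, rng, lo_ax, hi_ax):
    vs = np.asarray(geometry.voxel_size_um)
    shape = np.asarray(geometry.shape)
    # soma centers only on shell voxels not already claimed by a neighbor
    free = shell_idx[~blocked[shell_idx[:, 0], shell_idx[:, 1], shell_idx[:, 2]]]
    if len(free) == 0:
        return None
    for _ in range(config.max_attempts):
        pick = free[rng.integers(len(free))]
        center = (pick + 0.5 + rng.uniform(-0.5, 0.5, size=3)) * vs
        try:
            if morphology == "ameboid":
                # volume uniform between the bounding spheres, then mild
                # volume-preserving shape anisotropy: cell volumes stay in a
                # bounded band with no long upper tail
                re_um = float(rng.uniform(lo_ax**3, hi_ax**3) ** (1.0 / 3.0))
                g = rng.uniform(-0.15, 0.15, size=2)
                axes = re_um * np.array([np.exp(g[0]), np.exp(g[1]), np.exp(-g[0] - g[1])])
                voxels = rasterize_ameboid(center, axes, _random_rotation(rng), geometry)
            else:
                # volume target drawn over the same band as the ameboid
                # population; branch thickness scales with the target so
                # large ramified cells grow thicker, not just longer
                v_lo = (4.0 / 3.0) * np.pi * lo_ax**3 / geometry.voxel_volume_um3
                v_hi = (4.0 / 3.0) * np.pi * hi_ax**3 / geometry.voxel_volume_um3
                target = int(rng.uniform(v_lo, v_hi))
                nb = int(rng.integers(config.n_branches_range[0], config.n_branches_range[1] + 1))
                cap = config.branch_len_um_range[1]
                # choose branch thickness so the branches can deliver the
                # volume target within the length cap: a tube of thickness t
                # rasterizes to ~0.85 * pi (t/2)^2 / voxel_volume voxels/µm
                soma_vox = (4.0 / 3.0) * np.pi * config.soma_radius_um**3 / geometry.voxel_volume_um3
                needed_rate = max(target - soma_vox, 0.0) / (nb * cap * 0.8)
                t_um = 2.0 * np.sqrt(needed_rate * geometry.voxel_volume_um3 / (0.85 * np.pi))
                t_lo, t_hi = config.branch_thickness_um_range
                voxels = rasterize_ramified(
                    center,
                    nb,
                    cap,
                    float(np.clip(t_um, t_lo, t_hi)),
                    rng,
                    geometry,
                    soma_radius_um=config.soma_radius_um,
                    wobble=config.branch_wobble,
                    target_voxels=target,
                )
        except ValueError:
            continue  # out of bounds or degenerate; retry
        if np.any(voxels < 0) or np.any(voxels >= shape):
            continue
        if len(voxels) < config.min_cell_voxels:
            continue
        if blocked[voxels[:, 0], voxels[:, 1], voxels[:, 2]].any():
            continue
        return voxels
    return None


def _per_region_counts(per_cell: pd.DataFrame, region_order: list[str]) -> pd.DataFrame:
    rows = []
    for name in region_order:
        sub = per_cell[per_cell["region"] == name]
        n_am = int((sub["morphology"] == "ameboid").sum())
        n_ram = int((sub["morphology"] == "ramified").sum())
        rows.append({"region": name, "n_ameboid": n_am, "n_ramified": n_ram, "n_total": n_am + n_ram})
    return pd.DataFrame(rows, columns=["region", "n_ameboid", "n_ramified", "n_total"])


def _render_channel(base, noise_sd, rng, geometry) -> IntensityVolume:
    base = np.asarray(base, dtype=np.float64)
    if noise_sd > 0:
        base = base + rng.normal(0.0, noise_sd, size=base.shape)
    values = np.clip(np.rint(base), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return IntensityVolume(values=values, geometry=geometry)


def simulate_raters(
    truth_mask: np.ndarray,
    n_raters: int,
    disagreement: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Imperfect rater masks from a reference segmentation.

    Human raters disagree mostly at object boundaries, so each rater
    flips voxels in the 1-voxel boundary band (dilation XOR erosion of
    the reference) independently with probability ``disagreement``.
    """
    if n_raters < 2:
        raise ValueError("need at least 2 raters")
    truth_mask = np.asarray(truth_mask, dtype=bool)
    band = ndi.binary_dilation(truth_mask, ndi.generate_binary_structure(3, 3)) ^ ndi.binary_erosion(
        truth_mask, ndi.generate_binary_structure(3, 3)
    )
    raters = []
    for _ in range(n_raters):
        flips = band & (rng.random(truth_mask.shape) < disagreement)
        raters.append((truth_mask ^ flips).astype(np.uint8))
    return raters
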