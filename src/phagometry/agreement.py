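"""Voxel-wise multi-rater agreement: Fleiss kappa.

Items are voxels, raters are independent segmentations of the same
stack, categories are segmentation labels (background included, so N is
the number of voxels of the stack unless a restriction mask is given).
With n_ij the number of raters assigning voxel i to category j:

    p0 = (sum_i sum_j n_ij^2 - N*n) / (N * n * (n - 1))
    p_j = sum_i n_ij / (N * n)          (marginal proportions)
    pe = sum_j p_j^2
    kappa = (p0 - pe) / (1 - pe)

kappa is 1 exactly when every voxel is rated unanimously (and more than
one category is in use); all ratings in a single category make pe = 1
and kappa undefined.

Two equivalent computation paths are provided: an explicit N x k
RatingMatrix, and a chunked accumulator over label maps that never
materializes the table, for whole-stack use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .volumes import LabelVolume

log = logging.getLogger(__name__)

__all__ = [
    "DegenerateAgreementError",
    "RatingMatrix",
    "AgreementResult",
    "PerStructureAgreement",
    "build_ratings",
    "fleiss_kappa",
    "fleiss_kappa_from_maps",
    "per_structure_kappa",
]


class DegenerateAgreementError(ValueError):
    """All ratings fall in one category: chance agreement is 1 and kappa
    is undefined."""


@dataclass
class RatingMatrix:
    """N x k table of per-voxel category counts across n raters."""

    counts: np.ndarray
    categories: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2D (N x k) array")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise TypeError("counts must be integers")
        if self.counts.size == 0 or self.counts.min() < 0:
            raise ValueError("counts must be non-negative and non-empty")
        row_sums = self.counts.sum(axis=1)
        if not np.all(row_sums == row_sums[0]):
            raise ValueError("every voxel must be rated by the same number of raters")
        if self.N < 1 or self.k < 2 or self.n < 2:
            raise ValueError(
                f"need N >= 1, n >= 2, k >= 2; got N={self.N}, n={self.n}, k={self.k}"
            )
        if not self.categories:
            self.categories = list(range(self.k))
        elif len(self.categories) != self.k:
            raise ValueError("categories length must equal the number of columns")

    @property
    def N(self) -> int:
        return self.counts.shape[0]

    @property
    def k(self) -> int:
        return self.counts.shape[1]

    @property
    def n(self) -> int:
        return int(self.counts[0].sum())


@dataclass
class AgreementResult:
    """Observed/chance agreement, marginals and kappa."""

    p0: float
    pe: float
    p_j: np.ndarray
    kappa: float


@dataclass
class PerStructureAgreement:
    """Binary (structure vs rest) kappas per structure with mean ± sd."""

    kappas: dict[str, float]
    mean: float
    sd: float


def build_ratings(
    label_maps: list[LabelVolume | np.ndarray],
    restrict_mask: np.ndarray | None = None,
) -> RatingMatrix:
    """Assemble the N x k rating table from aligned label maps.

    The category set is the union of labels present across maps
    (background 0 included when present); rows are voxels (within
    ``restrict_mask`` if given) and each row sums to the number of maps.
    """
    arrays = [_as_array(m) for m in label_maps]
    if len(arrays) < 2:
        raise ValueError(f"need at least 2 label maps, got {len(arrays)}")
    shape = arrays[0].shape
    for i, a in enumerate(arrays[1:], start=2):
        if a.shape != shape:
            raise ValueError(f"map {i} shape {a.shape} does not match map 1 shape {shape}")
    if restrict_mask is not None:
        restrict_mask = np.asarray(restrict_mask, dtype=bool)
        if restrict_mask.shape != shape:
            raise ValueError(f"restrict_mask shape {restrict_mask.shape} does not match {shape}")
        flat = [a[restrict_mask] for a in arrays]
    else:
        flat = [a.ravel() for a in arrays]
    categories = np.unique(np.concatenate([np.unique(f) for f in flat]))
    N = flat[0].size
    counts = np.zeros((N, len(categories)), dtype=np.int64)
    for f in flat:
        idx = np.searchsorted(categories, f)
        np.add.at(counts, (np.arange(N), idx), 1)
    return RatingMatrix(counts=counts, categories=[int(c) for c in categories])


def _as_array(m) -> np.ndarray:
    a = m.labels if isinstance(m, LabelVolume) else np.asarray(m)
    if not np.issubdtype(a.dtype, np.integer):
        a = a.astype(np.int64)
    return a


def _kappa_from_sums(N: int, n: int, sum_sq: float, col_sums: np.ndarray) -> AgreementResult:
    p0 = (sum_sq - N * n) / (N * n * (n - 1))
    p_j = col_sums / (N * n)
    pe = float(np.sum(p_j**2))
    if 1.0 - pe <= 0.0:
        raise DegenerateAgreementError(
            "degenerate agreement: all ratings fall in a single category (pe = 1)"
        )
    kappa = (p0 - pe) / (1.0 - pe)
    return AgreementResult(p0=float(p0), pe=pe, p_j=p_j, kappa=float(kappa))


def fleiss_kappa(ratings: RatingMatrix) -> AgreementResult:
    """Fleiss kappa of an explicit rating matrix."""
    counts = ratings.counts.astype(np.float64)
    sum_sq = float(np.sum(counts**2))
    col_sums = counts.sum(axis=0)
    return _kappa_from_sums(ratings.N, ratings.n, sum_sq, col_sums)


def fleiss_kappa_from_maps(
    label_maps: list[LabelVolume | np.ndarray],
    restrict_mask: np.ndarray | None = None,
    chunk_voxels: int = 1 << 20,
) -> AgreementResult:
    """Fleiss kappa over label maps without materializing the N x k table.

    Accumulates sum(n_ij^2) and the category marginals in chunks;
    results are identical to the RatingMatrix path.
    """
    arrays = [_as_array(m) for m in label_maps]
    if len(arrays) < 2:
        raise ValueError(f"need at least 2 label maps, got {len(arrays)}")
    shape = arrays[0].shape
    for i, a in enumerate(arrays[1:], start=2):
        if a.shape != shape:
            raise ValueError(f"map {i} shape {a.shape} does not match map 1 shape {shape}")
    if restrict_mask is not None:
        restrict_mask = np.asarray(restrict_mask, dtype=bool)
        flat = [a[restrict_mask] for a in arrays]
    else:
        flat = [a.ravel() for a in arrays]
    categories = np.unique(np.concatenate([np.unique(f) for f in flat]))
    k = len(categories)
    if k < 2:
        raise DegenerateAgreementError(
            "degenerate agreement: all ratings fall in a single category (pe = 1)"
        )
    N = flat[0].size
    n = len(flat)
    sum_sq = 0.0
    col_sums = np.zeros(k, dtype=np.float64)
    for start in range(0, N, chunk_voxels):
        stop = min(start + chunk_voxels, N)
        counts = np.zeros((stop - start, k), dtype=np.int32)
        rows = np.arange(stop - start)
        for f in flat:
            idx = np.searchsorted(categories, f[start:stop])
            np.add.at(counts, (rows, idx), 1)
        sum_sq += float(np.sum(counts.astype(np.float64) ** 2))
        col_sums += counts.sum(axis=0)
    return _kappa_from_sums(N, n, sum_sq, col_sums)


def per_structure_kappa(
    label_maps: list[LabelVolume],
    structures: list[str],
    restrict_mask: np.ndarray | None = None,
) -> PerStructureAgreement:
    """Binary kappa per structure (structure vs everything else).

    Each map is binarized to {structure, not-structure} (k = 2) before
    the kappa computation; structures absent from every map are skipped
    with a warning.  Mean and sample sd are taken across structures.
    """
    kappas: dict[str, float] = {}
    for structure in structures:
        binaries = []
        present = False
        for m in label_maps:
            mapping = m.name_to_label
            if structure in mapping:
                b = (m.labels == mapping[structure]).astype(np.uint8)
                present = present or bool(b.any())
            else:
                b = np.zeros(m.labels.shape, dtype=np.uint8)
            binaries.append(b)
        if not present:
            log.warning("structure %r absent from every rater map; skipped", structure)
            continue
        kappas[structure] = fleiss_kappa_from_maps(binaries, restrict_mask=restrict_mask).kappa
    values = np.array(list(kappas.values()), dtype=float)
    if values.size == 0:
        raise ValueError("no structure was present in any rater map")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return PerStructureAgreement(kappas=kappas, mean=mean, sd=sd)
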