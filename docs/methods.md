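# Methods

This note documents the models, conventions, parameters and design
choices behind `phagometry`, and what the synthetic validation does and
does not demonstrate about real data.

## Conventions

**Axis order and coordinates.** Everything is `(z, y, x)`, 0-based.
Voxel `(i, j, k)` spans the physical box `[i·sz, (i+1)·sz) × …` and its
center sits at `((i+0.5)·sz, (j+0.5)·sy, (k+0.5)·sx)` µm.  NIfTI files
(stored `(x, y, z)`) are transposed at load.  Anisotropic voxel sizes
are supported throughout; every physical quantity uses the per-axis
sizes.

**Rasterization rule.** A voxel belongs to a continuous shape iff its
*center* lies inside the shape (closed boundary, tolerance 1e-9).  The
phantom generator and the hull computation share this rule, which is
what makes the solidity of convex digital shapes exactly 1.

## Segmentation pipeline

The marker channel is masked per ROI before thresholding.  Dilation of
an ROI by radius `r` µm keeps every voxel whose center is within `r` of
some ROI voxel center (computed with an exact Euclidean distance
transform using the per-axis voxel sizes).  The dilation radius is the
single most influential free parameter: it defines how far beyond the
anatomical surface the periductal cuff is searched.  The module default
is 12 µm (about one cell radius); phantom runs use 56 µm because the
default phantom's cells extend up to ~52 µm beyond the duct surface
(shell offset + longest branch), and a mask that clips cells would bias
every downstream measure.  Both µm and voxel units are supported.

Otsu's threshold is computed over in-mask voxels only — the masked-out
zeros would otherwise dominate the histogram and pull the threshold to
the background.  Foreground is strictly above the Otsu threshold; a
fixed threshold keeps voxels at or above it.  Components are labeled at
26-connectivity (face, edge or corner adjacency) by default, with
deterministic label order (raster-scan order of each component's first
voxel).

Filtering runs in a fixed order: objects with fewer than
`min_object_voxels` voxels (default 100, strict `<`) are removed first;
volume outliers second, so the outlier statistic is computed on the
size-filtered population.  The outlier rule is explicit and one-sided:
an object is removed iff its voxel count exceeds
`median + k · 1.4826 · MAD` (default `k = 3`); only the upper tail is
touched because the artifacts this step exists for are oversized merges
of several cells or labeling debris.  Degenerate situations (fewer than
3 objects, or MAD = 0) are no-ops with a logged warning rather than
errors.  `min_object_voxels` is in voxels by definition; a `min_object_um3`
alternative converts through the voxel volume for cross-resolution use.

## Morphometry

Volume is `Vm = voxel_count × voxel_volume` exactly.  Solidity is
`Vm / Vh` computed **in voxel space**: `Vh` is the number of voxel
centers inside or on the convex hull of the object's voxel centers
(half-space tests against the Qhull facets, tolerance 1e-9).  Counting
centers rather than integrating the polytope makes solidity exactly 1
for convex digital shapes — cuboids, digital balls, straight lines —
and keeps it in (0, 1] always.  Degenerate sets (rank < 3: points,
lines, planar sets) take the convention that the hull rasterizes to the
set itself, so their solidity is 1; for 26-connected objects this is
exact for collinear sets and a deliberate simplification for coplanar
ones, which do not occur for cells of realistic size.  A `continuous`
hull mode is available for sensitivity analysis: there `Vh` is the
physical volume of the hull of the voxel *corner* points, which equals
the true physical volume for filled boxes.

The equivalent radius is the radius of the sphere with the cell's
volume, `r = (3V / 4π)^(1/3)`, computed per cell and then averaged per
region (not derived from the mean volume).

Morphology is classified by a single solidity threshold, default 0.5:
ramified iff solidity < 0.5, ameboid at or above.  The default sits
midway between typical exemplars of the two classes (branched cells
score ~0.1-0.3, compact cells ~0.7-1.0) and is configurable; the
threshold used is recorded in the run provenance.

Region assignment is nearest-ROI by physical center-to-center distance
from any cell voxel; ties break lexicographically on the region name,
and cells farther than `max_distance_um` from every ROI are
"unassigned".  `max_distance_um` defaults to the masking dilation
radius so that assignment and masking delimit the same compartment.
Occupancy is the fraction of a (dilated) ROI's voxels covered by
segmented cells.  Summary tables report mean and sample sd (n−1); a
single-cell region reports sd 0 with an explicit `sd_defined = False`
flag, and the "All" row aggregates every cell including unassigned
ones (also reported as their own row).

## Fleiss kappa

Items are voxels, raters are aligned segmentations, categories are the
union of labels present (background included), so N is the voxel count
of the stack unless a restriction mask is given.  With `n_ij` raters
assigning voxel `i` to category `j`:

```
p0 = (Σ_i Σ_j n_ij² − N·n) / (N·n·(n−1))
p_j = Σ_i n_ij / (N·n)
pe = Σ_j p_j²
kappa = (p0 − pe) / (1 − pe)
```

`p_j` is the standard marginal-proportion definition.  If all ratings
fall in a single category, `pe = 1` and the computation raises a
dedicated degeneracy error instead of returning a number.  Two
computation paths exist — an explicit N×k rating matrix, and a chunked
accumulator of `Σ n_ij²` and the marginals that never materializes the
table — with a tested contract that they agree; whole stacks use the
chunked path.  Per-structure mode binarizes each map to
{structure, rest} (k = 2) and reports per-structure kappas with their
mean ± sd across structures; both whole-stack and per-structure
aggregations are exposed because either can be the quantity of interest.

## Phantom generator

The generator emulates the geometry this pipeline targets: tubular
ducts/vessels in a dark background, each wearing a single-layer cuff of
macrophages, imaged as a marker channel (cells bright over constant
background) plus a decorative structure channel (tube walls).  Noise is
additive Gaussian, clipped and rounded to uint16 — enough to stress
thresholding without modeling light-sheet optics, PSFs or
autofluorescence texture.

Default study conditions: a 160 × 320 × 256 µm block at 2 µm isotropic
voxels; two parallel tubes of 10 µm radius 128 µm apart ("ed", "vva");
10 ameboid + 10 ramified cells per tube, placed by rejection sampling
(≤1000 attempts per cell) with soma centers within 10 µm of the tube
surface and at least one empty voxel between cells, so noise-free
segmentation at 26-connectivity recovers them one-to-one.  Marker
intensity 200 over background 10; the noisy validation condition uses
`noise_sd = 19` (10% of that contrast).

Cell morphologies:

- **Ameboid** cells are rotated ellipsoids.  The volume is drawn
  uniformly between the 8 µm and 11.5 µm equivalent-radius spheres
  (~2.1-6.4 × 10³ µm³, bracketing radii observed for periductal
  macrophages), then mild volume-preserving shape anisotropy
  (log-factors ±0.15) and a uniform random rotation are applied.
  Rasterized convex ellipsoids have solidity exactly 1.
- **Ramified** cells are a 6 µm soma plus 5-8 branch tubes grown as
  random walks (step half a voxel, persistent direction with a wobble
  term), stamped by the voxel-center rule so each branch is
  26-connected.  Branches grow round-robin until the cell reaches a
  volume target drawn uniformly over the *same* band as the ameboid
  population, with branch thickness (2.5-5.5 µm) chosen analytically
  from the target (a tube of thickness t yields ≈ 0.85·π(t/2)²/voxel
  volume voxels per µm) and length capped at 40 µm.  Their solidity is
  below ~0.3 at these defaults.

Two consequences of this design are load-bearing.  First, the two
morphologies differ sharply in solidity (gap > 0.7 on average, far
above the 0.25 the validation requires) while sharing one volume
distribution — as in tissue, where volume is similar across
morphologies.  Second, because the shared volume distribution is
uniform on a bounded band, its maximum stays below the
`median + 3·1.4826·MAD` outlier cutoff (verified over 60 seeds:
max/cutoff ≤ 0.97), so the outlier filter — which must stay armed,
since it is part of the pipeline under test — does not delete genuine
cells and exact noise-free recovery is achievable.  A generator with a
long-tailed volume distribution would make "recover the truth exactly"
unsatisfiable by the pipeline's own defaults, which is a statement
about the phantom, not the pipeline.

Ground truth is exact by construction: per-cell labels are the
rasterized voxel sets themselves, and the truth tables (voxel count,
solidity, region, morphology) are computed from those sets with the
same conventions the morphometry module uses.

Simulated raters for the agreement stage flip voxels only in the
1-voxel boundary band of the reference mask (dilation XOR erosion),
each with probability `disagreement` (default 0.2) — mimicking human
raters, who disagree at object boundaries rather than uniformly at
random.

**What passing phantoms does not show.** The phantom has constant
background, no intensity gradients, no touching cells, no partial-volume
effects and no anisotropic PSF.  Results on real stacks will depend on
threshold quality and manual refinement in ways the phantom cannot
probe; the phantom validates the measurement chain (geometry handling,
labeling, hulls, statistics), not the biology of any particular stack.

## Numerical choices

- Half-space and distance comparisons use a 1e-9 absolute tolerance;
  dilation uses `distance <= r + 1e-9` so boundary voxels are included
  deterministically.
- Label order after connected components is the raster-scan order of
  each component's first voxel; filters preserve relative order while
  recompacting to 1..M.
- Otsu on a two-level histogram returns the lower level; foreground is
  strictly above, so exact two-level phantoms binarize exactly.
- The top-level seed fans out via fixed offsets (phantom: `seed`,
  simulated raters: `seed + 1`, all mod 2³¹) through NumPy
  `SeedSequence` spawning, making every stage independently
  reproducible; reports carry the seed and a config hash, and repeated
  runs are byte-identical.

## Problem sizes used in validation

Unit tests run on ≤ 64³ volumes with brute-force oracles (lattice
counting, BFS flood fill, Delaunay hull membership, exact rational
kappa).  End-to-end validation uses the default phantom (40 cells,
1.6 M voxels) once noise-free and across 20 seeds at 10% contrast
noise.  These sizes keep the full suite in the minutes range on one
CPU while exercising every code path at realistic cell scale.

## Known limitations

- The rasterized hull count is O(bounding-box volume) per cell; very
  large elongated objects are slower than compact ones.
- Voxel-space solidity differs from physical-space solidity under
  anisotropy; the default mirrors binarized-stack practice, and the
  continuous mode exists to quantify the difference.
- The MAD outlier rule assumes a unimodal-ish volume distribution;
  strongly bimodal populations could flag genuine large cells.
- `per_structure_kappa` requires structures to be findable by name in
  each rater's label table; disjoint naming across raters is treated
  as absence.
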