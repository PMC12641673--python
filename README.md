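# phagometry

Volumetric quantification of macrophages around narrow inner-ear ducts
and vessels in cleared-tissue light-sheet stacks.

Tissue clearing (iDISCO-style) plus light-sheet microscopy produces 3D
image stacks in which a pan-macrophage immunolabel (e.g. Iba1) can be
segmented around anatomical structures such as the reuniting duct (RD),
the endolymphatic duct (ED) and their companion vessels.  `phagometry`
implements the full analysis chain for such data as a tested, scriptable
pipeline:

1. **ROI masking** — anatomical ROIs arrive as integer label maps
   (ITK-SNAP-compatible NIfTI, with an `index<TAB>name` sidecar); each
   ROI is dilated by a physical radius so the periductal macrophage cuff
   stays inside the mask, and the marker channel is zeroed outside it.
2. **Segmentation** — Otsu (or fixed) thresholding over in-mask voxels,
   connected-component labeling at 26-connectivity, removal of objects
   with fewer than 100 voxels (strict `<`), and removal of upper-tail
   volume outliers by a `median + 3 x 1.4826 x MAD` rule.
3. **Morphometry** — per cell: volume `Vm` (voxel count scaled by the
   voxel volume), convex-hull volume `Vh` (rasterized hull: voxel
   centers inside the hull of the cell's voxel centers), solidity
   `Vm / Vh`, equivalent-sphere radius `(3V / 4π)^(1/3)`, centroid,
   nearest-ROI region assignment, and an ameboid/ramified morphology
   call (ramified iff solidity < 0.5).  Solidity is 1 exactly for
   convex digital shapes and low for branched cells, which is what
   makes it a morphology classifier.
4. **Summaries** — per-region tables (count, solidity, volume, radius,
   mean ± sd) and ROI occupancy (fraction of an ROI's voxels covered by
   segmented cells).
5. **Agreement** — voxel-wise multi-rater Fleiss kappa,
   `kappa = (p0 - pe) / (1 - pe)` with
   `p0 = (ΣΣ n_ij² - N·n) / (N·n·(n-1))` and `pe = Σ p_j²`, over whole
   stacks or binarized per structure.

Because real cleared-tissue stacks of this kind are rarely public, the
package ships a first-class **phantom generator**: two-channel synthetic
stacks containing tubular ducts with periductal cuffs of ellipsoidal
(ameboid) and branched (ramified) cells, with exact voxel-level ground
truth.  Every stage of the pipeline is validated end to end against
that truth.

## Worked example

```python
from phagometry.pipeline import default_phantom_run_config, run_pipeline

cfg = default_phantom_run_config(seed=1, simulate_raters=3, output_dir="out")
report = run_pipeline(cfg)
print(report.summary.round(3).to_string(index=False))
print(report.occupancy.round(4).to_string(index=False))
print("kappa:", round(report.kappa["whole_stack"]["kappa"], 3))
```

prints

```
region  n_cells  solidity_mean  solidity_sd  volume_mean_um3  volume_sd_um3  radius_mean_um  radius_sd_um  sd_defined
    ed       20          0.566        0.446           4595.2       1362.829          10.201         1.120        True
   vva       20          0.574        0.438           4379.6       1525.328          10.013         1.211        True
   All       40          0.570        0.437           4487.4       1431.867          10.107         1.155        True
roi  occupancy
 ed     0.0214
vva     0.0204
kappa: 0.616
```

Reading: the noise-free default phantom holds 20 cells around each of
two ducts ("ed", "vva"); all 40 are recovered.  Mean solidity ~0.57
mixes fully solid ameboid cells (solidity 1.0) with branched ramified
cells (solidity ~0.1), volumes and equivalent radii (~10 µm) are in the
range typical of tissue macrophages, the cells cover ~2% of each
dilated periductal compartment, and three simulated raters with
boundary disagreement agree at kappa 0.62.

The same stages are available as CLI subcommands (`phagometry
simulate | mask | segment | measure | agree | run`), driven by a YAML
config; `run` writes `cells.csv`, `summary.csv`, `occupancy.csv`,
`kappa.csv` and a provenance-stamped `report.json`, and re-running the
same config and seed reproduces them byte for byte.

## Layout

- `src/phagometry/volumes.py` — geometry and volume containers
- `src/phagometry/stack_io.py` — TIFF/NIfTI readers and writers
- `src/phagometry/phantom.py` — synthetic phantom generator
- `src/phagometry/masking.py` — ROI extraction, dilation, masking
- `src/phagometry/segmentation.py` — threshold, label, filter
- `src/phagometry/morphometry.py` — solidity, radius, regions, summaries
- `src/phagometry/agreement.py` — Fleiss kappa
- `src/phagometry/pipeline.py`, `cli.py` — orchestration and CLI

See `docs/methods.md` for the model, parameter and design notes.
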