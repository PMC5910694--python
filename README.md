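# myoarch

Three-dimensional muscle architecture from diffusion-tensor MRI.

`myoarch` reconstructs muscle fascicles from a diffusion-tensor volume and a
compartment segmentation by deterministic streamline tractography, fits cubic
curves to the tracts, extrapolates them linearly to the muscle surface, and
derives per-compartment architecture: fascicle length, 3D pennation angle,
Frenet–Serret curvature, compartment volume and physiological cross-sectional
area (PCSA), plus change-with-lengthening statistics from linear mixed models.
A pennate-muscle phantom generator with analytic ground truth stands in for
MRI scans.

## Modules

| Module | Role |
| --- | --- |
| `myoarch.phantom` | Synthetic slab phantoms: per-voxel tensors following straight or circular-arc fibre fields, DWI synthesis (Rician noise), compartment masks, closed surface meshes, analytic truth |
| `myoarch.dti` | Log-linear least-squares tensor fit, eigen-decomposition, FA/MD, direction-encoded RGB maps |
| `myoarch.geometry` | Label volumes → closed surface meshes, volumes (divergence theorem), muscle long axis and length, seed/boundary tracking masks, segmentation reliability |
| `myoarch.tract` | Deterministic bidirectional streamline tracking with FA/MD windows (0.1–0.5, 1–2 × 10⁻³ mm²/s), 10° angle limit, 1 mm steps, 15–200 mm length bounds |
| `myoarch.fascicle` | Cubic polynomial fits, linear extrapolation to the surface mesh, extension filters (< 20 mm and < 50% of length), pennation/curvature/length/PCSA, digitised-polyline metrics |
| `myoarch.arch_stats` | Compartment × condition summary tables, posterior volume fraction, per-cm-of-lengthening changes, REML random-intercept mixed models with Wald contrasts |
| `myoarch.cli` / `myoarch.pipeline` | Click CLI, YAML-configured pipeline, run manifests, NIfTI/STL/PLY/TCK/VTK/CSV I/O |

## CLI

One entry point with a subcommand per stage:

```sh
# generate the four-compartment phantom (tensors, DWI, labels, meshes, truth)
myoarch phantom --out scratch/phantom --seed 1

# fit tensors from DWI + FSL-style bval/bvec
myoarch fit-dti --dwi scratch/phantom/dwi.nii --bvals scratch/phantom/dwi.bval \
    --bvecs scratch/phantom/dwi.bvec --out scratch/dti

# surfaces, tracking, fascicle analysis
myoarch surfaces --labels scratch/phantom/labels.nii --out scratch/surf
myoarch track --tensors scratch/phantom/tensors.nii --labels scratch/phantom/labels.nii \
    --out scratch/tracts --n-target 1000 --seed 7
myoarch fascicles --streamlines scratch/tracts/streamlines_1.tck \
    --mesh scratch/phantom/compartment_1.ply --compartment MA --out scratch/fasc

# aggregate subject records into the summary table
myoarch summarise --records records.csv --subjects subjects.csv --out scratch/summary

# or run everything from a YAML config
myoarch run --config config.yaml --seed 1
```

A pipeline run writes FA/MD/RGB NIfTI volumes, per-compartment surface
meshes, per-fascicle CSVs, a per-compartment records CSV and a `manifest.json`
recording the config hash, seed and per-stage counts; identical config + seed
reproduces outputs byte-for-byte.

## Notes

* All geometry is in world millimetres; voxel indices are 0-based; a voxel is
  inside a mask when its centre is.
* The extension filter is interpreted as: total extension (both ends) < 20 mm
  and < 50% of the final fascicle length (fit + extensions); this is recorded
  in each run manifest.
* Curvature is evaluated on the fitted polynomial only (extensions are
  straight), at 100 points equidistant in arc length.
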