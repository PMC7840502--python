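# cubecyte

Cube-based spatial image cytometry for 3D fluorescence images of microbial
communities — biofilms, colonies and free-floating aggregates.

## The problem

Confocal stacks of biofilms rarely allow single-cell segmentation, yet the
biology of interest — matrix production, reporter gradients, strain mixing,
growth — varies strongly *inside* the community. Classical whole-biofilm
tools (COMSTAT and kin) reduce a stack to a handful of global numbers and
lose all internal spatial structure.

`cubecyte` takes the middle road: the segmented biofilm biovolume is
dissected into a cubical grid of user-defined edge length (squares for 2D
images), and each occupied cube becomes a *pseudocell* — the unit of a
flow-cytometry-style analysis with spatial coordinates attached. Per cube
it computes structural, fluorescence, texture and correlation parameters
(49 in total with two channels); per biofilm it computes COMSTAT-compatible
structure metrics, channel colocalization and 3D spatial correlation
functions. Cube subpopulations can be gated, combined into custom
parameters, tracked over time, and rendered as kymographs or exported to
ParaView.

## The method in brief

1. **Segmentation** — the stack is filtered (median/Gaussian, physically
   sized) and thresholded with Otsu, Ridler–Calvard iterative intermeans,
   robust background (trimmed mean + k·sd), maximum-correlation
   thresholding, or a manual level; pre-segmented binary or labeled masks
   can be imported instead. Foreground is intensity strictly above the
   level.
2. **Dissection** — voxels are partitioned into cubes of edge `e` µm
   (`span = round(e / pitch)` voxels per axis; truncated edge cubes are
   kept and flagged). Every foreground voxel belongs to exactly one cube.
3. **Cube cytometry** — per cube: fill fraction (local density),
   biovolume, centroid, distance to the outer surface / substratum /
   center of mass, local thickness, exposed surface area; intensity
   statistics per channel; gray-level co-occurrence texture; channel–
   channel Pearson/Spearman/Manders correlations and a density–intensity
   correlation over the 27-cube neighborhood.
4. **Global metrics** — biovolume, mean/max thickness, substratum
   coverage, roughness coefficient Ra\* = ⟨|Lᵢ − L̄|⟩/L̄ over occupied
   columns, face-counted surface area (COMSTAT convention) plus a
   marching-cubes mesh area, colocalization (Pearson, MOC, M1/M2, overlap
   fractions, relative abundances), and shell-averaged 3D correlation
   functions with cluster-size (1/e crossing) and separation
   (first cross-correlation maximum) summaries.
5. **Time series** — rigid xy drift registration, positional cube-lineage
   tracking (largest-overlap parent), clonal cluster sizes, and
   spatiotemporal kymographs (parameter × distance bin × time or
   biovolume).

A seeded synthetic-colony generator (hemispheres, slabs, wrinkled
macrocolony slabs, spheres, strain mixtures, growth series with reporter
fields) makes the whole pipeline testable without any image downloads.

## Worked example

```python
import numpy as np
from cubecyte import *
from cubecyte.synthgen import SynthSpec, make_colony, add_intensity_field

geom = VoxelGeometry(dx=0.25, dy=0.25, dz=0.25)          # µm per voxel
spec = SynthSpec(shape="hemisphere", volume_voxels=(40, 80, 80),
                 geometry=geom, seed=11, radius_um=8.0)
mask = make_colony(spec)                                  # ground-truth biovolume
reporter = add_intensity_field(                           # exp(-d/2 µm) reporter
    mask, {"type": "exp_decay_from_surface", "lam_um": 2.0, "amplitude": 100.0},
    seed=12, channel_name="1")
constitutive = add_intensity_field(
    mask, {"type": "constant", "value": 100.0},
    noise={"gaussian_sd": 3.0}, seed=13, channel_name="2")

grid = build_cube_grid(mask, edge_um=1.0)
table = assign_voxels(mask, grid)
quantify_all(table, mask, [reporter, constitutive])
print(f"cubes: {len(table)}, parameters per cube: {len(table.parameters)}")

gm = global_structure(mask)
print(f"biovolume: {gm['biovolume_um3']:.1f} um3")
print(f"mean thickness (biomass columns): {gm['mean_thickness_biomass_um']:.2f} um")
print(f"roughness coefficient: {gm['roughness_coefficient']:.3f}")

k = kymograph([table], "ch1_mean", "dist_surface_um", bin_um=0.5)
col, w = k.values[:, 0], k.weights[:, 0]
ok = ~np.isnan(col) & (col > 0) & (w > 50)
lam = -1.0 / np.polyfit(k.y_centers[ok], np.log(col[ok]), 1)[0]
print(f"recovered reporter decay length: {lam:.2f} um (imposed: 2.00 um)")
```

Output:

```
cubes: 1292, parameters per cube: 49
biovolume: 1073.2 um3
mean thickness (biomass columns): 5.32 um
roughness coefficient: 0.300
recovered reporter decay length: 2.04 um (imposed: 2.00 um)
```

The hemisphere of radius 8 µm has analytic volume (2/3)π·8³ ≈ 1072.3 µm³;
the digitized biovolume agrees to 0.1 %. The 1292 occupied 1 µm cubes each
carry the full 49-parameter set, and the depth profile of the synthetic
reporter recovers the imposed 2 µm decay length from the kymograph column.

## Command line

```sh
cubecyte synth    --config run.yaml --seed 7   # synthetic dataset (TIFF + mask)
cubecyte all      --config run.yaml            # segment → cubes → global → VTK
cubecyte segment  --config run.yaml            # masks only
cubecyte track    --config run.yaml            # lineage edge list
cubecyte kymograph --config run.yaml
```

The YAML config holds the voxel geometry, input image manifest, and the
`segmentation`, `cubes`, `cytometry`, `global` and `timeseries` sections;
unknown keys are rejected. Every run writes a `provenance.json` with the
config hash and chosen thresholds. Cube tables and global metrics are CSV;
grids are exported as legacy ASCII VTK `STRUCTURED_POINTS` files loadable
in ParaView.

## Documentation

See `docs/methods.md` for the precise definitions, conventions
(axis order, surface treatment at the substratum, histogram and tie-break
policies), the synthetic-data model, and known limitations.
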