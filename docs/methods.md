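# Methods

This note records the models, conventions and numerical choices behind
`cubecyte`, in the order of the pipeline. Everything stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is an
external claim.

## Conventions

* Arrays are indexed `(z, y, x)`; `z = 0` is the plane adjacent to the
  substratum (attachment surface). This makes "distance to substratum" a
  pure z computation.
* Coordinates are 0-based; the center of voxel `(z, y, x)` sits at
  `((z+0.5)·dz, (y+0.5)·dy, (x+0.5)·dx)` µm. Voxel geometry is always
  supplied explicitly (config), never read from TIFF resolution tags,
  which are unreliable across export pipelines.
* `NaN` is the universal missing-value token; gates exclude NaN records
  from both a gate and its complement.
* 2D images are carried as `(1, ny, nx)` volumes and dissected into
  squares (z span 1).

## Segmentation

Filtering converts a physical size (µm) to per-axis voxel extents, so the
kernel is isotropic in physical space on anisotropic stacks. Thresholding:

* **Otsu** — maximize the between-class variance
  σ_b²(t) = ω₀ω₁(μ₀ − μ₁)² over the interior edges of a 256-bin
  equal-width histogram spanning [min, max]. Ties break toward the lowest
  level; the first argmax of the scan realizes this.
* **Ridler–Calvard** — iterate T ← (mean(I ≤ T) + mean(I > T))/2 from the
  global mean until the change is below `tol` (default 10⁻⁶ of the
  intensity range; hard cap 1000 iterations).
* **Robust background** — drop the dimmest and brightest 5 % of voxels,
  level = mean + 2·sd of the remainder. The trim fraction and k are
  exposed; this family of estimators is defined differently across tools,
  so the concrete formula is fixed and documented here.
* **Maximum correlation** — the level maximizing the Pearson correlation
  between gray values and their binarization, scanned over the same
  256-bin edges, lowest maximizer.

Foreground is *strictly greater* than the level — a manual level equal to
the image maximum therefore yields an empty mask, an unambiguous
convention. Despeckling removes 26-connected components below
`min_object_voxels` (8-connected in 2D); hole filling is per-z-slice (2D),
never 3D, so genuine vertical channels through the biofilm are not sealed.
Otsu/MCT levels are affine-equivariant: rescaling intensities by a·I + b
rescales the level and leaves the mask unchanged (tested).

## Dissection

Cube edge length is given in µm and converted per axis to
`span = round(edge/pitch)` voxels (minimum 1). Cube regions are the
half-open index ranges `[i·s, min((i+1)·s, n))`; edge cubes may be
truncated and are kept with a flag, with the truncated region size as the
fill-fraction denominator (padding to full cubes would bias density at the
rim). The partition is exact: summed per-cube foreground equals the mask
total, and summed per-cube biovolume equals the global biovolume to
machine precision.

Imported labeled masks bypass the grid: each label becomes one record
whose region is its own voxel set (fill fraction 1), so object-level
cytometry flows through the same table machinery. Grid-dependent
parameters (neighborhood, gradients, density correlation) are NaN for such
tables.

## Per-cube parameters

With two channels the set totals 49:

| family | count | members |
|---|---|---|
| geometry | 13 | fill_fraction, foreground_voxel_count, biovolume_um3, centroid_{x,y,z}_um, dist_surface_um, dist_substrate_um, dist_com_um, dist_com_projected_um, local_thickness_um, exposed_surface_area_um2, local_surface_to_volume_um |
| neighborhood | 5 | occupied_neighbor_count, neighborhood_mean_fill, fill_gradient_magnitude, relative_height, dist_surface_normalized |
| intensity | 8 × 2 | mean, sd (population), cv, median, min, max, sum, range |
| texture | 5 × 2 | GLCM contrast, correlation, energy, homogeneity, entropy |
| correlations | 3 + 2 | pairwise Pearson, Spearman, MOC; density correlation per channel |

All cube statistics run over the cube's **foreground voxels only** — they
describe biomass, not background; fill fraction alone uses the region
denominator.

**Distances.** `d_surface` is the anisotropy-aware Euclidean distance
transform of the foreground to the nearest background voxel. The volume is
padded with background on all faces except z = 0: in `attached` mode the
substratum contact is not outer surface (the base of a surface-attached
biofilm contributes no surface distance); `floating` mode (aggregates)
pads all six faces. A cube's `dist_surface_um` is the mean over its
foreground voxels (robust for partially filled cubes, unlike centroid
sampling). The transform is verified against an O(n²) brute-force
nearest-background search in both modes.

**Local thickness.** Column height follows the COMSTAT convention
`(1 + top foreground z index)·dz`, ignoring interior gaps; a cube's local
thickness is the mean height over the distinct xy-columns it occupies.

**Texture.** Intensities are quantized per cube to 8 equal levels between
the cube's min and max; co-occurrence pairs are voxel pairs at ±1 voxel
offset along each axis (pooled, symmetric, normalized). Cubes with fewer
than 8 foreground voxels, or without any adjacent foreground pair, get NaN.
A constant cube has a single co-occurrence cell: energy 1, contrast 0,
homogeneity 1, entropy 0, correlation NaN (zero marginal variance).

**Density correlation.** A within-cube density is a single number, so the
density–intensity correlation is computed across the cube's occupied
26-neighbors plus itself: Pearson between neighbor mean intensity and
neighbor fill fraction, NaN with fewer than 3 points.

**Gradients.** The fill-fraction gradient uses central differences on the
cube grid with unoccupied/outside neighbors counted as density 0 and the
realized cube edge (µm) as step; it recovers a constructed linear ramp to
1e-12.

**Custom parameters** are arithmetic expressions (`+ − × ÷ ^`, unary
minus, parentheses, `log log10 exp sqrt abs`) over existing parameter
names, parsed by a small recursive-descent parser with positional error
messages and near-match suggestions for typos. Division by zero and
logarithms of non-positive values yield NaN per record.

## Global metrics

Roughness Ra\* = (1/N)Σ|Lᵢ − L̄|/L̄ over occupied columns (0 for a flat
slab; 0.5 for the 1 µm/3 µm two-column toy). Two mean-thickness variants
are emitted (all columns vs. occupied columns) because COMSTAT
distinguishes them. Surface area is face-counted (foreground faces
adjacent to background, substratum face excluded in attached mode) for
COMSTAT compatibility; on a digitized sphere this systematically
overestimates the smooth area by ≈1.5× (voxel-face bias — tested as a
ratio in [1.45, 1.55]), so a marching-cubes mesh area is emitted
alongside as `surface_area_mesh_um2`.

Colocalization runs over mask voxels: Pearson, MOC = ΣAB/√(ΣA²ΣB²),
Manders M1/M2 with binarization levels defaulting to per-channel Otsu of
the within-mask intensities, binarized overlap fractions, and relative
abundances (which sum to 1 exactly).

**Correlation functions.** Indicator fields are centered over the analysis
window; the covariance at every integer voxel lag is divided by the number
of valid in-window pairs at that lag (no periodic wraparound — imaging
windows are not periodic), then shell-averaged by physical lag length
(anisotropy-aware) into bins of width dr, pair-count weighted. Bin 0 holds
the zero lag alone, so the normalized autocorrelation is exactly 1 at
r = 0. The FFT implementation is checked against a direct-sum oracle to
1e-10. Cluster size is the linearly interpolated 1/e crossing of the
autocorrelation; separation distance is the first local maximum of the
cross-correlation at r > 0. Both are estimator concretizations — the
quantities are standard, the estimators are this package's documented
choices. Caveat: full-3D shell averaging of strongly anisotropic patterns
(e.g. 1D-periodic slabs) shifts apparent maxima outward; for such
geometries a window collapsed along the uniform axes gives the clean
estimate (this is how the tests validate the estimator).

## Time series

Registration estimates a rigid integer xy drift per step as the argmax of
the centered 2D cross-correlation of z-projected (voxel-count) masks,
bounded by `max_shift`, with ties broken toward the smallest displacement
(a colony growing symmetrically therefore registers zero drift). There is
no z registration: surface-attached biofilms grow upward but do not
translate vertically; tracking should be disabled for floating aggregates.

Cube identity across frames is positional on the fixed grid after drift
correction. Parent→child edges connect cubes sharing at least one
foreground voxel; each child keeps its single largest-overlap parent with
a lowest-id tie-break, so lineages are deterministic and the graph is a
forest. Clonal clusters are 26-connected components of cubes dominated
(≥ `min_fraction` of the two-channel mean signal) by one strain; sizes sum
member biovolumes.

Kymograph cells are foreground-voxel-weighted means of a cube parameter
within distance-coordinate bins, per frame — weighting prevents sparse rim
cubes from dominating a bin. The x axis is the frame index or the frame's
total biovolume (a monotone reparametrization of time for growing
biofilms). Ratio kymographs (e.g. reporter over constitutive channel) set
cells with non-positive or NaN denominators to NaN and take the minimum of
the two weights.

## Synthetic data

The generator produces the geometries the analysis targets: surface-
attached hemispheres (radius 8 µm at 0.25 µm voxels in the standard
fixtures — ~69 000 foreground voxels, large enough for stable statistics,
small enough for second-scale tests), flat and wrinkled slabs (bimodal
thickness 4/8 µm for gating analyses), floating spheres, cubic-patch
strain mixtures, and nested growth series with optional integer drift.
Reporter fields are evaluated exactly on the same distance transform the
cytometry uses, so recovered decay lengths are directly comparable to the
imposed ones. Noise is additive Gaussian and/or Poisson, seeded; all
outputs are pure functions of (spec, seed).

What the generator does **not** emulate: the microscope point-spread
function, depth-dependent attenuation, shot-noise calibration, cell-scale
granularity, or deconvolution artifacts. Passing tests therefore
demonstrate the correctness of the measurement machinery on known ground
truth, not segmentation robustness on adversarial real images — for real
data the import path for externally segmented masks exists precisely
because segmentation quality dominates downstream accuracy.

## Degenerate inputs and numerical edges

* Constant images: automatic thresholds raise a degenerate-input error
  advising a manual level.
* Empty masks: distance fields and global structure raise; cube
  assignment returns an empty table with a warning.
* Single-voxel cubes: sd 0, cv 0 (when mean > 0), texture NaN.
* Quantiles use linear interpolation (numpy default); summary sd is the
  population sd.
* CSV round-trips use `%.17g` and round-trip float parsing, reproducing
  values bit-exactly.
* Cube statistics and tables are byte-deterministic for fixed inputs;
  the CLI writes a config hash and chosen thresholds to
  `provenance.json`.

## Known limitations

* The per-cube parameter list is this package's reconstruction of the
  standard cube-cytometry families (structural, textural, fluorescence,
  correlation) at the canonical two-channel total of 49; other tools'
  lists differ in member identities.
* Tracking is positional (grid-space) with rigid xy drift correction; it
  does not handle deformable motion, z drift, or merge/split
  classification.
* Only TIFF is read; proprietary microscope formats should be converted
  first. VTK output is legacy ASCII `STRUCTURED_POINTS` (hand-inspectable
  and byte-stable, at the cost of file size).
* Face-counted surface areas carry the documented ≈1.5× voxelization bias
  on smooth surfaces; use the mesh area when absolute areas matter.
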