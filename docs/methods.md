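# Methods

This note documents the models, conventions, parameter defaults and design
decisions behind `radperturb`, in the order data flows through the package.

## Coordinate and data model

Images are 3D scalar arrays indexed `(x, y, z)` with per-axis spacing in mm;
the centre of voxel `(i, j, k)` is `origin + index·spacing`. All geometric
parameters are physical (degrees, mm, fractions of the spacing), never raw
indices, because clinical CT is anisotropic before interpolation (in-plane
≈0.9–1 mm, slices 2–5 mm). Intensities are Hounsfield units; NIfTI-1 is the
reference I/O path, with a DICOM-series reader (rescale slope/intercept
applied, uniform slice spacing enforced) behind the same interface.

ROI polygons (RTSTRUCT-style per-slice contours in mm) are rasterised by the
voxel-centre rule under the even–odd (ray crossing) fill; multiple polygons
on one slice combine by XOR so nested contours cut holes. Polygons are
snapped to the nearest slice within half a slice spacing — sub-slice offsets
beyond that are a geometry error. Self-intersecting polygons are reported
but still filled even–odd. The partial-volume threshold does **not** apply
here; it applies only when an already-voxelised mask is interpolated.

## Synthetic phantoms

`PhantomSpec`/`generate_phantom` produce ellipsoidal ROIs with constant,
linear-ramp or seeded random-texture interiors plus optional additive
Gaussian noise, as a pure function of the spec (seed included). The mask is
exact by the voxel-centre rule. The cohort generator
(`make_synthetic_cohort`) varies ROI size (default semi-axes from radii
8–14 mm), mean density (20–80 HU) and texture spread (30–90 HU) across
subjects — the axes along which real tumours differ — and draws independent
noise per replicate to emulate short-interval re-acquisition.

What the phantoms deliberately do *not* emulate: partial-volume blur at the
lesion boundary, spatially correlated reconstruction noise, anatomy outside
the ROI, scanner/kernel differences between test and retest. Tests passing
on phantoms therefore validate the *machinery* (operators, processing,
formulas, statistics), not clinical robustness values, which must come from
real cohorts.

## Perturbation operators

Fixed application order regardless of chain label:
rotation → noise → translation → (isotropic interpolation) → volume
adaptation → contour randomisation. R/T act on the native grid and carry the
mask as fractional occupancy; V/C act on the binarised mask of the
interpolated grid. Chains permute every parameter grid (full Cartesian
product); translation fractions are additionally permuted over the three
axes (m fractions → m³ shifts).

* **Rotation** — affine in-plane (axial) rotation in physical coordinates,
  trilinear resampling, about the ROI centre of mass by default (keeps the
  tumour in-grid; grid centre available via `centre="image_center"`).
* **Noise** — i.i.d. Gaussian with σ estimated from the image. The estimator
  is the 3D Laplacian pseudo-residual (sum of per-axis second differences,
  normalised by √42, the root of the kernel's coefficient sum of squares)
  summarised by 1.4826·MAD. Second differences annihilate constant and
  linear structure, and the MAD suppresses edge residuals, so the estimate
  tracks noise rather than anatomy. σ is estimated **once per input image**
  and reused for every repetition in a chain: repetitions are meant to be
  draws around the same acquisition, and re-estimating on already-noised
  images would compound σ.
* **Translation** — sub-voxel shift by η·spacing per axis, trilinear.
* **Volume adaptation** — rank selection on the signed Euclidean distance
  map of the mask boundary: the `round((1+τ)·N₀)` voxels with smallest
  signed distance (ties broken by flat index) form the output. This is the
  exact form of thresholding the distance map — monotone in τ, deterministic,
  superset for growth and subset for shrinkage — without a bisection loop.
* **Contour randomisation** — SLIC supervoxels over the ROI bounding box
  plus a 4-voxel margin, on min-max normalised intensities with compactness
  0.05 and a target supervoxel volume of 150 voxels of the working grid
  (a scale that needs revisiting for other modalities or very small ROIs; it
  is a config knob). A supervoxel with fractional overlap f against the
  original mask is kept always when f ≥ 0.9, with probability f when
  0 < f < 0.9, never when f = 0 — the ROI core survives, the rim is
  randomised. Deterministic per seed.

Default parameter domains (θ ∈ [−13°, 13°], η ∈ [0, 0.75],
τ ∈ [−0.28, 0.28]) trigger validation *warnings* when exceeded, never
errors. The 18-chain registry ships default grids whose expansion sizes are
the standard per-chain counts (27–40 perturbed images); the exact grid
values are package defaults, overridable per chain.

Per-sample seeds derive from SHA-256 of (base seed, chain label, parameter
tuple), truncated below 2³¹ — independent streams and bit-exact replay of
any sample from its provenance.

## Processing

* **Interpolation** — per-axis Gaussian pre-smoothing only where
  downsampling occurs, with σ = β·(s_target/s_source)/π in source-voxel
  units and β = 0.93, i.e. β is the preserved band fraction at the target
  Nyquist frequency; then trilinear resampling onto a centre-aligned
  isotropic grid (defaults 1, 2, 3, 4 mm). Upsampling is never smoothed.
* **Rounding** — intensities to nearest integer HU, halves away from zero
  (bit-reproducible across platforms, unlike round-half-even conventions).
* **Mask thresholding** — fractional occupancy ≥ 0.5 → foreground.
* **Re-segmentation** — intensity mask = morphological mask ∩ HU window
  (default [−300, 200]; use [−150, 180] for head-and-neck) ∩ |HU − μ| ≤ 3σ,
  where μ, σ are computed on the window-filtered ROI and the σ rule is
  applied once, not iterated. Order matters: filtering the window first
  keeps air/bone from corrupting μ and σ.
* **Discretisation** — fixed bin number `g = min(N_b, ⌊N_b(x−min)/(max−min)⌋+1)`
  over the ROI's own range (constant ROI → level 1); fixed bin size
  `g = ⌊(x−lo)/w⌋+1` anchored at the window minimum `lo`, so grey levels are
  comparable across ROIs. Defaults: N_b ∈ {8, 16, 32, 64}, w ∈ {6, 12, 18, 24} HU.

## Features

182 base features in 11 families; 118 require discretisation
(IH 23, GLCM 25, GLRLM 16, GLSZM 16, GLDZM 16, NGTDM 5, NGLDM 17) and are
computed per spacing × discretisation setting; 64 do not (morphology 29,
local intensity 2, intensity statistics 18, IVH 15) and are computed per
spacing only: 64×4 + 118×4×8 = 4032 per image by default. The IVH family
uses intensity/volume fractions at 10/25/50/75/90%, two difference pairs and
the AUC of the volume-fraction curve, evaluated at 1 HU resolution
independent of the discretisation settings.

Conventions that change values and are therefore pinned here:

* Morphology meshes come from marching cubes at level 0.5 on the mask after
  a 0.8-voxel Gaussian smooth; the raw binary isosurface overestimates
  curved surface area by ~8% (staircase artefact), while the smoothed
  isosurface reproduces a 10 mm sphere's area to <1% and volume to ~1.5%.
  Principal axes use the population covariance of voxel centres. The
  oriented bounding box comes from the mesh's minimal oriented box, the
  minimum-volume enclosing ellipsoid from Khachiyan's algorithm on the
  convex hull vertices, ellipsoid areas from the Thomsen approximation
  (p = 1.6075). Moran's I / Geary's C use inverse-distance weights and a
  deterministic stride-subsample above 1000 ROI voxels.
* Local/global intensity peaks average over a 1 cm³ spherical neighbourhood
  (radius 6.204 mm).
* Texture matrices are 3D: GLCM distance 1 (Chebyshev), symmetric, and
  GLRLM runs, both computed per each of the 13 unique directions with
  features averaged afterwards; GLSZM/GLDZM zones are 26-connected with
  city-block zone distances (border voxels at distance 1, array edge padded
  as border); NGTDM/NGLDM use the 26-neighbourhood, NGLDM with α = 0 and
  dependence-count columns indexed count+1 (run-length-like, 1-based).
* Degenerate cases return the defined limit where one exists (e.g. GLCM
  correlation → 1 for a single grey level, constant ROI → histogram level 1)
  and otherwise a flagged NaN with a reason code — never a silent zero that
  would leak into the ICC.

## Robustness statistics

ICC(1,1) from the one-way ANOVA decomposition; MSW = 0 with MSB > 0 gives
exactly 1 (CI [1, 1], flagged); an all-constant panel is undefined and
classified indeterminate. Negative estimates are retained — classification
compares CI bounds, and truncation would bias the CI averaging. The 95% CI
follows Shrout–Fleiss (F₀ = MSB/MSW, F-quantile bounds mapped through
(F−1)/(F+k−1)), clipped to [−1, 1]. "CI ≥ threshold" is read as the lower
bound test: the entire interval at/above 0.90 — the only reading consistent
with a three-state scheme. With two replicate images the perturbation
ICC and both CI bounds are averaged element-wise; if either side is
undefined the feature is indeterminate. Subjects with any missing value for
a feature are dropped listwise for that feature (counts logged); α = 0.05
and the 0.90 threshold are configurable.

## Pipeline and reproducibility

`run_robustness` writes per-sample features, per-chain ICC tables, a
robust/non-robust/indeterminate summary per chain, and (with two replicates)
the T±/P± comparison table, plus a log with config hash, seeds, chain
expansion counts and per-stage failures. Runs are byte-identical under a
fixed base seed. Perturbed volumes are not persisted by default.

Test and example problem sizes are deliberately desk-scale — phantoms of
24³–64³ voxels, one or two spacings, reduced discretisation grids and small
cohorts — chosen so the whole suite exercises every code path in minutes
while the statistics remain well-conditioned; all counts scale by
configuration, not code.

## Known limitations

Only axial rotations; no elastic deformation or scanner/reconstruction
simulation; no 2D feature variants, filtered-image features or modelling
strategies downstream of the robustness table; MVEE/OMBB are iterative/
approximate (documented above); clinical robustness fractions require real
cohorts and are out of scope for the phantom-based validation.
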