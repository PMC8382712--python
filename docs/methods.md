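# Methods

This note documents the models, parameter choices and numerical
conventions behind `mcts_nucleus`, and what the synthetic phantoms do
and do not establish about real microscope data.

## Coordinate and unit conventions

All volumes are `(z, y, x)`-ordered; every physical quantity is in µm,
µm² or µm³. Voxel coordinates are voxel-center and 0-based; exported
tables carry µm. Default voxel spacing is (0.9, 0.4393, 0.4393) µm —
a confocal stack acquired with 0.9 µm optical sections chosen so that
roughly two-fold z-interpolation yields isotropic voxels at the
lateral pitch.

## Segmentation

The pipeline is a three-stage marker-controlled watershed:

1. **Initial segmentation** — z-interpolation to isotropic voxels
   (linear; x–y planes untouched), Gaussian smoothing, local adaptive
   threshold, hole filling and small-object removal, distance-transform
   seeding, watershed.
2. **Seed correction** — seeds whose objects are below
   `small_seed_fraction` (0.7) of the median object volume are removed;
   objects above `oversize_fraction` (1.4) of the median are flagged as
   merged clusters and their seeds may be replaced by caller-supplied
   points (a CSV of label → voxel coordinates stands in for interactive
   clicking, keeping runs headless and reproducible).
3. **Final watershed** on the corrected seed set. The second and third
   watersheds re-run on the full volume rather than only affected
   clusters; with a deterministic flooding order this is equivalent for
   unaffected objects and much simpler to reason about.

Parameters, with defaults and rationale:

| parameter | default | meaning / why |
|---|---|---|
| `gaussian_sigma` | 0.35 µm | noise suppression before thresholding; ≈0.8 interpolated voxel. Calibrated on phantoms: larger values stack onto the optical blur and widen the segmented halo around each nucleus. |
| `window_fraction` | 0.5 | local-mean window spans half the stack per axis, i.e. window volume = stack volume/8 — the only separable reading of "an eighth of the stack volume" consistent with a mean filter. Windows are clipped at borders (true mean over the in-bounds part). |
| `threshold_offset_fraction` | 0.15 | the local mean of a field that is mostly background sits far below the nuclear boundary half-maximum, so thresholding at the plain local mean wraps every nucleus in a blur halo (≈2× volume). The threshold is raised by this fraction of the smoothed stack's 99th percentile — scale-free, so it survives detector-gain changes. The absolute `threshold_offset` (default 0) remains available. |
| `hmin_depth` | 1.5 µm | H-minima suppression depth on the (negated, µm-valued) distance transform; deeper merges seeds. Calibrated on phantoms; oversegmentation is preferred since small-fragment pruning and cluster re-seeding repair it, while missed splits only surface through the oversize flag. |
| `min_object_volume` | 50 µm³ | far below any 2N nucleus (~800 µm³); removes debris and threshold speckle. |
| `connectivity` | 26 | for components and regional minima; watershed ties resolve by deterministic scan order. |

The threshold uses a strict ">" (with a 10⁻⁵-relative epsilon
absorbing float roundoff) so a constant image yields an empty
foreground.

## Per-nucleus measurements

* **Volume** = voxel count × voxel volume.
* **Surface area** — marching-cubes mesh area. Voxel-face counting
  overestimates a sphere by ~50% and even a raw marching-cubes mesh of
  a binary mask by ~8–10% (staircase facets), which would push
  sphericity of real spheres to ~0.92; the mask is therefore smoothed
  with a 0.8-voxel Gaussian before meshing at level 0.5, giving ≤1%
  area error for nucleus-sized objects. Objects too small to survive
  the smoothing are meshed raw.
* **Principal axes** — eigendecomposition of the voxel-coordinate
  covariance (second central moments, µm²) plus the finite-voxel
  correction spacing²/12 per axis. A solid ellipsoid of semi-axis *a*
  has moment λ = a²/5, so the reported full axis is 2√(5λ); eigenvector
  signs are fixed (first nonzero component positive). Coplanar regions
  are rejected by `principal_axes` itself; `measure_nuclei` falls back
  to the finite-voxel moments for degenerate few-voxel labels so a
  record is still produced.
* **Extent** = volume / axis-aligned bounding box. Note the discrete
  convention: a digital ball of radius r spans 2r+1 voxels per axis, so
  its extent is π/6·(2r/(2r+1))³, about 7% below the continuous π/6 at
  r = 20.
* **Integrated intensity** is summed on the *raw* (unsmoothed) stack:
  smoothing redistributes intensity across nucleus boundaries and would
  bias DNA content of touching nuclei.
* **Volume gate** — nuclei outside 60–180% of the median volume
  (inclusive bounds, for determinism) are split off but returned, since
  the large-volume tail (fused objects, polyploid nuclei) is itself of
  interest.

## DNA-content analysis

* **Depth correction** — even cleared specimens lose signal with
  depth. Integrated intensity is fitted against centroid depth per
  spheroid: medians in 5 µm depth bins (robust to the 4N minority and
  bright artifacts), weighted least squares with bin-occupancy weights
  (the sparse top/bottom bins otherwise dominate through leverage).
  Corrected value = raw × fit(z_ref)/fit(z) with z_ref the spheroid's
  shallowest nucleus; the reported `relative_slope` = slope/intercept
  is the fractional loss per µm referred to zero depth. Spheroids with
  <10 nuclei or <20 µm depth span get an identity correction and a
  warning.
* **Normalization** — corrected intensity / per-spheroid median;
  pooling across spheroids only after normalization, which removes
  stain and detector gain differences. Spheroids with <3 nuclei are
  excluded.
* **Peak location** (`fit_dna_histogram`) — the classic univariate
  DNA-cytometry decomposition: Gaussian G0/G1, Gaussian G2/M, flat
  S-phase plateau between the peaks (stopping one sigma short of each
  so it cannot absorb them), and a broad uniform background for
  debris/doublet-like outliers, fitted by EM with deterministic
  initialization. The G2/G1 mean ratio is constrained to [1.85, 2.15],
  standard practice since stoichiometric staining pins replicated DNA
  at twice the diploid amount. Raw histogram/KDE argmax mislocates a
  small G2 peak sitting on the S-phase shoulder; the mixture fit does
  not.
* **FUCCI classing** — RFP⁺/GFP⁻ → G1, GFP⁺/RFP⁻ → S/G2, both → G1/S,
  neither → non-transfected. Positivity is strict ">" against a
  per-channel threshold: either explicit, or mean + 3·SD of the
  background population (intensities up to twice the histogram mode —
  the non-transfected majority). Ties (exactly at threshold) are
  negative. Two transfection-efficacy conventions exist; both are
  implemented (`positive_to_negative`, `positive_to_total`).
* **Threshold classifier** — S/G2 iff content strictly exceeds the
  threshold; the optimal threshold maximizes TPR − FPR on a 0.01-step
  grid over [0.5, 3.0], ties toward the larger threshold.
* **SVM** — RBF kernel, soft margins, balanced class weights (G1 ≫
  S/G2). Features: the seven volumetrics each normalized by the mean of
  the five nearest same-spheroid nuclei (removing the radial size/shape
  trend so the classifier cannot learn position), plus the corrected,
  normalized DNA content un-normalized by neighbors. Hyperparameters
  (C, γ over log-spaced grids) by 5-fold cross-validated search
  maximizing balanced accuracy on a stratified 80% training split; the
  report comes from the untouched 20%. A Bayesian optimizer would be an
  interchangeable search vehicle; the grid is deterministic and
  seedable. All stochastic steps take explicit seeds.

## Spatial organization

The spheroid body is the union of nuclei closed with a Euclidean ball
(`closing_radius` 10 µm ≈ the inter-nuclear gap scale), implemented
exactly via two distance transforms, hole-filled, largest component
kept. The center is the centroid of this mask (robust to uneven
nuclear density). Nuclei with centroids outside the body are
"detached" and excluded. Perimeter distance is the interior distance
transform at the centroid voxel. Layers are half-open, lower-inclusive
10 µm shells with distances ≥60 µm pooled innermost; radial trends use
half-open 5 µm bins (mean ± SD or median ± MAD, bins with <3 nuclei
flagged). The alignment angle is computed as arcsin|r̂·ê₃| — the angle
between the center-to-nucleus direction and the plane of the major and
intermediate axes, numerically stable at both 0° and 90°. For
isotropically oriented ellipsoids |r̂·ê₃| is uniform on [0, 1], so α
has CDF sin α: median 30°, mean ≈32.7°. The z-alignment angle replaces
r̂ with the optical axis; a linear fit of each principal-axis length
against it quantifies the axial-resolution artifact as a length
difference between 0°- and 90°-aligned nuclei.

## The synthetic phantom

`PhantomSpec` defaults emulate the target preparation: a 70 µm-radius
spheroid of 300 ellipsoidal nuclei with full axes 16.3/11.8/8.2 µm
(SD 2.3/1.4/1.2), voxels (0.9, 0.4393, 0.4393) µm, class fractions
G1 0.813 / G1-S 0.070 / S-G2 0.117, transfection rate 0.252.

* **Packing** — dart throwing with collision tests on a 1 µm occupancy
  grid against each candidate's rendered shape shrunk 10% linearly, so
  neighbors end up near-touching (which is what stresses the
  watershed). Exclusion-sphere packing was rejected: at these densities
  bounding-sphere exclusion corresponds to a ~34% sphere packing
  fraction, beyond what random sequential placement can reach.
* **DNA content** — G1 and G1/S at content 1; S/G2 cells half at 2
  (G2/M) and half uniform on (1.1, 1.9) (S phase). Stain stoichiometry
  jitter: lognormal-like 6% CV. A 12% minority of nuclei carries a
  bright-tail artifact (intensity × (1 + Exp(0.4))), a monotonically
  decaying tail toward 4N emulating doublet-like staining/segmentation
  errors; calibrated so ≈6% of 2N nuclei exceed content 1.25, the
  false-positive tail a plain threshold classifier suffers. Nuclear
  volume couples to content (volume × (1 + 0.5(c − 1))), so 4N nuclei
  are ~1.5× larger — the signal the SVM exploits.
* **Optics** — per-voxel intensity = stain/voxel-count (stoichiometric
  total), linear depth attenuation 0.004 per µm, anisotropic Gaussian
  blur (0.6, 0.3, 0.3) µm, additive Gaussian noise (SD 4 against
  ~200-count nuclei), optional Poisson stage. Each nucleus's rendered
  shape is additionally elongated 2 µm along z (an explicit stand-in
  for axial PSF smearing), and this elongation is part of the ground
  truth: the truth table stores both nominal and effective
  (post-elongation) axes and orientations.
* **FUCCI channels** — rendered for transfected nuclei only: G1 RFP,
  S/G2 GFP, G1/S both at 60%, with 20% lognormal expression jitter.
  Blur produces realistic cross-talk between touching nuclei, which is
  why a few FUCCI calls are "wrong" relative to the simulated class —
  as in real data.

**What phantom results do not show.** The phantom has no real PSF, no
spectral bleed-through, no autofluorescent background, no necrotic
core (spheroids of this size do not develop one), no aneuploidy
continuum and no nuclear texture. Passing recovery tests demonstrates
the pipeline's internal consistency and its behavior under the stated
noise/blur/attenuation model — not performance on any particular
microscope's data, which additionally depends on clearing quality and
staining protocol.

## Problem sizes used in validation

Segmentation recovery runs on the single full-size default phantom
(300 nuclei, ~48M interpolated voxels). Cohort-level analyses
(DNA-peak recovery, threshold-versus-SVM comparison, orientation
controls) use 10–20 spheroids of radius 50 µm with 110 nuclei each —
the same nuclear packing density as the default — measured on
ground-truth labels so they probe the intensity/classification stages
independently of segmentation error, which the recovery test
quantifies separately.

## Known limitations

* The adaptive threshold needs the offset calibration above when
  images have near-zero background; data with substantial diffuse
  background may behave well at offset 0.
* Depth correction is linear; strongly scattering (uncleared)
  specimens would need an exponential model.
* The seed-correction stage is only as good as the supplied
  replacement points; fully automatic operation leaves clusters that
  the oversize flag identifies but nothing splits.
* `fit_dna_histogram` assumes a dominant diploid population; heavily
  polyploid samples violate its initialization.
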