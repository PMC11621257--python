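# Methods

## Quantification model

CTpfav is a pure threshold volumetric: a voxel contributes iff it lies in
the lung mask **and** its attenuation falls in the fat window, a closed
interval with both endpoints inclusive. The default window is
[−200, −60] HU; some densitometry work uses −40 HU as the upper bound, so
both bounds are exposed (`HUWindow`, `--hu-low/--hu-high`). The choice of a
closed interval is isolated in one predicate (`HUWindow.contains`) and is
the only place the convention lives.

Assumptions and deliberate simplifications:

- **Whole-voxel counting.** A voxel is in or out by its HU value; no
  partial-volume weighting. Voxels at tissue interfaces (vessel/parenchyma,
  pleura/parenchyma) can average into the fat window; this is a known bias
  of threshold densitometry and is reported, not corrected.
- **No structure exclusion.** Vessels, airways and endobronchial mucus
  inside the lung mask are not masked out.
- **PFI is undefined on an empty lung region.** `compute_pfi` raises rather
  than returning 0 or NaN — a silent zero would corrupt downstream cohort
  statistics. The one exception is an empty *compartment* inside
  `compartment_quant` (e.g. no voxel deeper than the chosen depth), which
  is reported with zero volumes and `pfi_pct = NaN` so the sibling
  compartment's result remains usable.

Geometry is sacrosanct: image and mask must agree in shape, spacing
(componentwise within 1e-4 mm, absorbing header float noise) and
orientation. Nothing is ever resampled; a mismatch is a refusal
(`GeometryMismatchError`, CLI exit code 3). This is stricter than typical
clinical pipelines document, and intentionally so: resampling changes
volumes, the quantity under study.

Volumes load through nibabel and are reoriented to one canonical
orientation (RAS) at load, so array axes are (x, y, z) in physical terms
regardless of on-disk layout; all reported quantities are
orientation-invariant, so the reorientation is safe. DICOM series are
assembled by sorting slices along the image-orientation normal; slice-gap
nonuniformity above 1% is an error (the volume would be ill-defined), and
missing rescale slope/intercept tags are an error — identity rescale is
never silently assumed.

## Subpleural compartmentalization

The subpleural compartment is the lung within `depth_mm` (default 10 mm ≙
1 cm) of the lung boundary. The signed distance map is the exact Euclidean
distance transform (scipy's Maurer-class implementation) with the voxel
spacing as sampling, composed as `outside − inside` so that lung voxels are
negative and background positive.

**Distance convention.** The magnitude at a voxel is the distance from its
center to the center of the nearest voxel of the opposite class. A lung
voxel touching the boundary therefore has distance −(smallest spacing), not
0, and a 30³ voxel cube at 1 mm with depth 10 mm has exactly the inner 10³
block as its nonsubpleural core. The brute-force oracle used in the tests
(nearest-background-voxel search over coordinates) pins this convention
down; the SimpleITK `SignedMaurerDistanceMap` of the *inverted* mask agrees
with it exactly on the interior and serves as an independent cross-check in
the suite. (ITK's own interior convention measures to the nearest boundary
*object* voxel, one voxel-shell less; the difference is absorbed by the
inversion.)

- The reference surface is the **entire** lung boundary — costal,
  mediastinal, diaphragmatic and hilar. No surface subsetting is attempted;
  the hilar inclusion is a sensitivity the `depth_mm` parameter does not
  remove, and users comparing against other definitions should know it.
- Both lungs are processed as one binary mask. For anatomically separated
  lungs this equals per-lung processing (verified for disjoint components
  in the tests).
- Interlobar fissures are never boundaries: the subpleural split always
  uses the merged lung mask, never lobe masks, since fissure-adjacent
  parenchyma is not subpleural in any anatomical sense.
- The subpleural condition is closed (≤ depth), and the subpleural and
  nonsubpleural masks are an exact disjoint partition of the lung —
  asserted on every phantom in the suite.
- Lobar analysis is independent of the compartment analysis; neither
  re-runs distances per lobe.

## Synthetic phantoms

The phantom emulates the attenuation *contrast structure* of a chest CT,
not its anatomy: two axis-aligned ellipsoid lungs in a soft-tissue
background (+40 HU), parenchyma at −850 ± 30 HU, optional cylindrical
vessels (+50 HU), spherical fat inclusions at −100 HU, optional global
i.i.d. Gaussian noise added last. Defaults keep parenchyma and soft tissue
at least 4 effective standard deviations outside the fat window, so false
fat voxels are negligible by construction (≈ 21 σ at the defaults). What it
does **not** emulate: real airway/vessel trees, fissure geometry, correlated
CT texture, reconstruction-kernel effects, partial-volume blur. Passing
tests therefore demonstrate the *computational* correctness of the pipeline
(counting, distances, units, statistics), not its robustness to clinical
image artifacts.

Conventions and choices:

- **Voxel-center rasterization**: a voxel belongs to a shape iff its center
  does. This makes the voxelized volume differ from the analytic one by at
  most (number of surface-crossing voxels) × (voxel volume), a bound the
  generator reports (`fat_surface_voxel_count`) and the tests assert.
- Problem sizes are desk-scale: ~10 cm lungs (~100 mL total) on 64³–80³
  grids at 1–1.5 mm spacing. All quantities of interest (recovery errors,
  PFI ratios, partition identities) are scale-free or have analytic
  references, so nothing depends on simulating a full-size thorax.
- Fat spheres may have explicit centers or be placed by rejection sampling
  (uniform in the lung, 2000 attempts, then `PlacementError`). Placement
  constraints — entirely within / entirely deeper than a given pleural
  depth, or inside a named lobe — are enforced against the *analytic*
  distance to the ellipsoid surface (solved exactly via the Lagrange
  condition with Brent root-finding) and re-verified against the discrete
  distance map in the tests. Spheres never overlap each other, keeping the
  analytic total volume exact.
- Ground truth (analytic sphere volumes, voxel-center counts, per-lobe and
  per-compartment classification of fat voxel centers) is computed from the
  geometry equations only, never from the HU image — agreement with the
  pipeline is a genuine two-implementation cross-check. Note the
  compartment ground truth uses the analytic surface distance, which
  differs from the discrete voxel-to-voxel distance by up to about half a
  voxel diagonal near the depth shell; tests compare it with a
  voxel-band tolerance.
- Lobes are assigned by axial cuts at fractional lung heights (left: 1 cut
  → LUL/LLL; right: 2 cuts → RUL/RML/RLL). Real lobar anatomy is oblique;
  for testing pooled-versus-averaged aggregation and additivity, planar
  cuts suffice.

### Simulated cohorts

`generate_cohort` draws, per subject, a lung-size scale factor and a PFI
target from lognormal distributions (median × exp(σ·Z)) and constructs fat
spheres summing to the implied volume (base radius 5 mm plus one remainder
sphere ≥ 2 mm; the dropped remainder bounds the construction shortfall by
~0.034 mL). The default three-group design is the package's reference
condition:

| group   | median PFI | log-σ(PFI) | lung scale | log-σ(scale) |
|---------|-----------:|-----------:|-----------:|-------------:|
| control | 1.0%       | 0.39       | 1.00       | 0.11         |
| COPD    | 0.5%       | 0.21       | 1.17       | 0.08         |
| fILD    | 2.0%       | 0.87       | 0.95       | 0.11         |

These emulate the clinically observed pattern for the contrast of interest:
a fibrotic group with elevated, heavy-tailed PFI and smaller lungs, an
obstructive group with enlarged lungs and low, tight PFI, and a control
between them. Scale factors are clipped to [0.7, 1.3] and PFI targets to
[0.05, 8]% so every sampled subject remains rasterizable on the template
grid and packable with disjoint spheres; the clips are far outside the
interquartile range and do not move the medians. Sampled targets are
recovered by the pipeline up to sphere-voxelization error (a few percent at
1.5 mm spacing).

## Statistics

- `dagostino_pearson` delegates to the standard K² implementation
  (scipy `normaltest`); n < 8 is an explicit error (the skewness transform
  is undefined), and 8 ≤ n < 20 carries a warning in the battery report.
- `kruskal_wallis` uses the tie-corrected rank statistic with a chi-square
  reference on k−1 df (scipy `kruskal`); the all-tied degenerate case is
  defined as H = 0, p = 1 instead of a division blow-up. The suite
  cross-checks H against a hand-ranked implementation of
  `H = [12/(N(N+1))·ΣR_i²/n_i − 3(N+1)] / (1 − Σ(t³−t)/(N³−N))`.
- `dunn_posthoc` is implemented here (no suitable implementation among the
  package's dependencies): pairwise z from pooled mid-rank means with the
  tie-corrected variance `N(N+1)/12 − Σ(t³−t)/(12(N−1))`, two-sided normal
  p-values, and Bonferroni-style adjustment `min(1, p·k(k−1)/2)` — the
  behavior of the common "Dunn's multiple comparison" implementations. The
  exact adjustment differs between software packages, so it is an explicit
  config option (`adjustment="bonferroni_style"`).
- `describe` uses linear interpolation between order statistics for the
  quartiles and reports both the (q1, q3) range and the width q3 − q1,
  since both reporting styles are common.
- `run_battery` always runs the nonparametric path and reports the
  normality results alongside for transparency; all p-values are two-sided,
  default α = 0.05.

Monte-Carlo calibration (type-I error of the omnibus test under an
exchangeable null, 1,000 replicates of 3 × 30) is asserted to lie in
[0.03, 0.07] — the binomial 3σ band around the nominal 0.05.

## Numerical notes

- All voxel-count identities (partition conservation, lobar additivity) are
  exact integer equalities; volume identities hold to ≤ 1e-9 mL (float
  summation only).
- The PFI identity `pfi_pct = 100·ctpfav/lungvol` is a single floating
  division and is tested to 1e-12 relative error.
- Point-to-ellipsoid distance: unique root of
  `Σ (a_i q_i/(a_i²+t))² = 1` on (−a_min², ∞), bracketed and solved with
  Brent's method (xtol 1e-10); on-axis degeneracies are nudged by 1e-9 mm.
- Determinism: every stochastic component (phantom noise, placement,
  cohort sampling) flows from one `numpy` Generator seeded by the spec or
  call; identical seeds give bit-identical arrays, tested by SHA-256.

## Known limitations

- Threshold densitometry cannot separate true fat from partial-volume
  artifacts; results on clinical data depend on reconstruction kernel and
  slice thickness in ways the phantom does not model.
- The subpleural definition includes the hilar/mediastinal surface; studies
  that exclude it will report lower subpleural PFIs.
- Lobe masks from automated segmentation inherit fissure-segmentation
  errors (the middle lobe is smallest and most error-prone); `lobar_quant`
  tolerates non-tiling lobes but cannot detect mislabeled ones.
- The cohort simulator reproduces group *contrasts*, not clinical absolute
  values; its medians are targets of construction, not predictions.
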