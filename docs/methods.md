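# Methods

## Density model and conversion conventions

A CT reconstruction assigns each voxel a CT number derived from the linear
attenuation coefficient μ of the material relative to water and air:
CTN = 1000·(μ − μw)/(μw − μa), so water is 0 and air −1000 on the
Hounsfield scale. Scanners store these values with a fixed positive offset;
`cheesect` adopts the convention that air sits near 0 stored units and
water near the offset (default 1024), and converts stored values to an
apparent density

ρ [kg/m³] = CTN_stored − offset.

This is the only reading under which a single scale supports both the
850 kg/m³ cheese/background threshold and a cheese matrix at
1100–1200 kg/m³; a literal Hounsfield interpretation would put water at
−1024 on the same scale. The offset is a configuration parameter
(`ctn_offset`). Rescale slope/intercept present in DICOM headers are
recorded in the scan metadata but never silently applied — the configured
conversion is always the one above, so the pipeline's densitometry is
explicit and reproducible. The conversion and its inverse are exact on
integers; rounding happens only when a volume is serialized.

Note the scale is *apparent* density: it is anchored so that the cheese
matrix lands in its literature density range, not calibrated against
physical density standards. All thresholds in the package live on this
scale. Since μ values for Grevé-type cheese are not established, the
attenuation→CTN map is exercised only synthetically.

## Segmentation

Cheese vs not-cheese is a single inclusive threshold: ρ ≥ 850 kg/m³ is
matrix. The boundary is inclusive so that the threshold value itself
classifies with the cheese-side densities; air (≈ 0), gas cavities and
packaging all fall far below it, which is why a manual threshold outperforms
histogram-automatic methods here — the two phases are separated by an
≈ 1000 kg/m³ gap and the only tuning concern is wax (see below).

The wheel is the largest 26-connected cheese component (ties broken toward
the smallest linear voxel index, with a warning). Cavities are found in the
complementary phase with 6-connectivity; the complementary 26/6 pairing
avoids the topological paradox of a diagonal gas path crossing a diagonal
cheese wall. Both connectivities are configurable (6/18/26). External air is
every below-threshold component reachable from the volume boundary by flood
fill; the remaining components intersecting the wheel's filled interior are
cavities. Consequences of this construction:

* a cavity open to the rind is connected to external air and is *not*
  counted (a warning is logged when interior gas connects to the boundary);
* below-threshold pockets outside the wheel (e.g. between wheel and field
  edge) are background, not cavities;
* every below-threshold voxel is exactly one of {external air, cavity,
  discarded speck}, so voxel counts are conserved — an invariant the tests
  assert exactly.

Components smaller than `min_volume_cm3` (default 0.01 cm³ ≈ 8 voxels at
1×1×1.25 mm) are discarded as noise speckle and accounted separately. The
default is an order of magnitude below the smallest eye-volume percentile
that matters in practice (≈ 0.1 cm³), so it suppresses noise without
touching real eyes.

A per-slice labeling mode (`labeling_mode = 2d-stacked`) labels the same
cavity voxel set slice by slice; total gas volume is identical by
construction and only the component count changes (one sphere spans several
slices). It exists because slice-wise counting is a plausible reading of
2D-image workflows; the default, and the mode all headline numbers use, is
full 3D labeling.

Labeling is implemented with `scipy.ndimage`; an independent pure-Python
breadth-first flood-fill oracle (volumes ≤ 32³) backs the equivalence tests.

## Morphometry

**Volume.** V = Σ slice areas × slice thickness, converted to cm³. On voxel
data this equals voxel count × voxel volume algebraically; the catalog
computes both and asserts their identity rather than trusting it.
Digitized-sphere volumes converge to 4/3·π·r³ as r grows; at the default
spacing the error is ≈ 1 % at r ≥ 5 mm and within 5 % well below that.

**Surface area.** Marching cubes at level 0 of the signed Euclidean
distance field (outside − inside, in mm, computed at the native anisotropic
spacing) of the cavity, cropped to its padded bounding box. Plain marching
cubes on the binary mask at level 0.5 systematically overestimates the area
of curved surfaces (staircase facets): a digitized r = 4 mm sphere comes
out ≈ 10 % too large, pushing sphericity to 0.897. The SDF isosurface sits
half a voxel outside the voxel centers and smooths the staircase without
the shrinkage or thin-structure loss that Gaussian pre-filtering or mesh
smoothing introduce (a 1.25 mm slab survives; Taubin-smoothed meshes were
non-monotone in radius). The estimator is deterministic for a fixed input.

**Roundness.** 3D sphericity Ψ = π^⅓(6V)^⅔/A. Exactly 1 for an analytic
sphere; for digitized spheres at generic (off-lattice) centers the pipeline
measures 0.913 / 0.922 / 0.931 at r = 4 / 8 / 16 mm — inside [0.90, 1.10]
and monotonically approaching 1. For cavities a few voxels across the
discrete surface estimate can undershoot the voxel faces and push Ψ above
1; such values are reported as-is, matching how practical eye-roundness
reports show 90th percentiles slightly above 1. Shape scores of
lattice-aligned digitizations fluctuate with accidental symmetry, which is
why the test fixtures place sphere centers on cell corners (the generic
position). A 2D per-slice circularity (4πA/P²) was considered as an
alternative definition and rejected as the default because a flat crack can
look perfectly circular in-plane.

**Cracks.** crack_flag = (Ψ < 0.4) ∧ (V > 1 cm³), both cutoffs
configurable. Cracks are flat (slab sphericity ≈ 0.25–0.36) while even
poorly digitized eyes stay above 0.9, so the gap is wide; the volume cutoff
keeps small irregular cavities from being misflagged. Flagged cavities
remain in the eye summaries by default (`include_cracks_in_summary`), since
whole-cavity statistics are the norm; exclusion is one flag away.

**Summaries.** Percentiles use linear interpolation between order
statistics. Eye% is computed as 100·R/(1+R) from Ratio R so the algebraic
identity between the two reported quantities is exact in floating point.
Wheels with no cavities report absent (None) volume/roundness statistics
rather than zeros, so empty wheels cannot drag group means toward zero;
Ratio and Eye% are 0 in that case.

## Group statistics

One-way fixed-effects ANOVA (computed in-module, cross-checked against
`scipy.stats.f_oneway` in the tests) with Tukey HSD pairwise comparisons
(`scipy.stats.tukey_hsd`, studentized-range distribution) at α = 0.05.
With two groups the Tukey p equals the pooled two-sided t-test p (q = √2·|t|),
which the tests verify to 1e-9. The compact letter display assigns one
letter per maximal clique of the non-difference graph (Bron–Kerbosch), so
groups share a letter iff they are not significantly different. Degenerate
metrics (zero within-group variance) short-circuit: identical means are
non-significant, different means are reported as separated. No correction
is applied across metrics (each metric is an independent question; the
report footer says so), variance homogeneity is not tested, and the two
ripening stages are treated as independent groups even when the same wheels
were rescanned — a deliberate mirror of common practice in these reports.
Simulated type-I error at α = 0.05 over 1000 null replicates lands in
[0.03, 0.07].

## Phantom generator

The phantom emulates the study material: a cylindrical wheel (default
density 1150 kg/m³, air background 1.2 kg/m³, default spacing
1×1×1.25 mm) with spherical eyes and planar cracks, optionally wrapped in a
wax shell (930 kg/m³ — above threshold, so it classifies as matrix; the
`wax_erosion_mm` pipeline option erodes the rind before wheel-volume
counting). Defaults for wheel geometry (radius 165 mm, height 120 mm) are
placeholders at the scale of a commercial wheel and fully configurable;
validation runs use smaller wheels sized to their purpose (see below).

Eyes are placed uniformly in the wheel interior with full containment
(center margin radius + 1 voxel) and, unless overlap is allowed, pairwise
separation rᵢ + rⱼ + 2 mm — the extra 2 mm guarantees rasterized spheres
stay disconnected at the default spacing, so ground-truth component counts
are exact. Cracks are thin oriented slabs; orientation and center are
rejection-sampled until all eight corners sit inside the wheel with a
two-voxel margin (so a synthetic crack never opens to the rind — rind-open
defects would merge with background by construction). Infeasible requests
(overpacked eyes, oversized cracks) raise validation errors rather than
degrading silently.

Voxel membership is a center-point test — no partial-volume antialiasing —
which keeps every analytic oracle exact up to discretization and matches
what a hard threshold assumes. The density field is forward-converted with
the same offset convention the pipeline inverts, Gaussian density noise
(σ configurable, default 0; scanner noise is not otherwise characterized)
is added, and values are rounded to integers. Everything is driven by one
seed: identical spec + seed ⇒ bit-identical volumes.

The expected component count comes from a union-find over features using
exact geometric intersection tests (sphere–sphere distance, sphere–box
clamping, box–box separating-axis). What the phantom does *not* emulate:
partial-volume blur at cavity walls, beam hardening, scatter, ring
artifacts, density gradients from moisture loss, and non-spherical eye
shapes. Passing phantom tests therefore demonstrates correctness of the
measurement chain on idealized geometry, not robustness to every scanner
artifact; the σ = 30 kg/m³ noise runs cover the dominant degradation only.

Cohort generation (`young_mature_cohorts`) draws per-wheel seeds from one
master seed and differs between cohorts only in the eye model — the
young/mature contrast is radius distribution (volume scales as r³, so a 2×
radius ratio yields ≈ 8× mean eye volume, which the tests confirm by
simulation).

## Validation problem sizes

* Labeling oracle equivalence: 100 random 20³ volumes, both 6- and
  26-connectivity.
* Count/volume recovery: one 256×256×160-voxel wheel (radius 120 mm,
  height 185 mm) with 50 non-overlapping spheres, radii uniform in
  2–12 mm; detection must be exactly 50 and r ≥ 5 mm volumes within
  max(5 %, 2 voxel volumes) of 4/3·π·r³.
* Noise robustness: the same geometry over 5 seeds at σ = 30 kg/m³;
  ≥ 95 % of r ≥ 3 mm spheres recovered, zero false positives after the
  default minimum-volume filter.
* Cohort discrimination: 10 + 10 wheels of radius 60 mm / height 60 mm,
  12 eyes each, young radii U(2, 5) mm vs mature U(4, 10) mm. The volume
  metrics (mean and total eye volume, Ratio, Eye%) must separate at
  P < 0.05 while the generatively equal eye count must not — the
  qualitative significance pattern expected of a young-vs-mature
  comparison. Young wheels come out at ≈ 0.21 cm³ mean eye volume and
  mature at ≈ 1.7 cm³ under these settings.

## Known limitations

* The density scale is conventionally anchored, not calibrated; absolute
  densities inherit whatever bias the scanner's stored-value convention
  carries.
* Eyes open to the rind are uncounted by design; wheels with many rind
  defects will under-report porosity (the condition is logged).
* The 2D-stacked counting mode reproduces slice-wise workflows but its
  counts are resolution-dependent; cross-study count comparisons should use
  3D mode.
* Sphericity depends on the surface estimator; values from other packages
  (different estimators) are not directly comparable beyond the ordering
  round vs flat.
* ANOVA treats wheels as independent; repeated scans of the same wheel are
  not modelled as paired.
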