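# Methods

## Scope and data model

The package quantifies *segmented* cryo-ET scenes; tracing, template
matching and segmentation are upstream and out of scope. A scene couples,
in one right-handed nm coordinate frame: filament centerlines (ordered 3D
polylines, labeled `assembly` or `nucleoid`), particle point sets, binary
compartment masks on a single isotropic voxel grid, and metadata (genotype,
lamella z-bounds, replicate, seed). Voxel index (i, j, k) addresses the
*center* of the voxel at `origin + voxel_size·(i, j, k)`; nm↔voxel
conversion happens only at the I/O boundary. Masks are MRC2014 (read and
written through gemmi), filaments and points are CSV, RELION-style STAR
particle tables are read-only, and a YAML manifest binds a scene directory.
Per the STAR convention used here, coordinates are voxels and the
pixel-size field is interpreted as nm/voxel; an explicit `pixel_size`
argument overrides the table.

## Orientation-order statistics

Each filament is walked by arc length and cut into consecutive,
non-overlapping fragments of exactly `fragment_length` (default 20 nm —
several filament widths of ~5 nm, yet short against observed bend radii;
every output table records the value used). Fragment endpoints are linear
interpolations on the polyline; the trailing remainder is discarded, so the
fragment count per filament is ⌊arc length / L⌋. A fragment contributes the
normalized chord between its endpoints, treated as *axial* data (v ≡ −v).

The mean orientation is the principal eigenvector of the second-moment
orientation tensor T = (1/M) Σ v vᵀ — the standard axial mean; a plain
vector average is ill-defined under sign flips. An exact tie of the top two
eigenvalues (within 1e-9) raises an error rather than returning an
arbitrary axis. Angles θ = arccos |v·n̂| fold into [0°, 90°].

Dispersion is summarized as the circular spread 1 − R̄ of the doubled
angles. For perfectly aligned axes it is 0; for isotropic 3D axes folded to
[0°, 90°] its expectation is 1 − √5/3 ≈ 0.255 (E[cos 2θ] = −1/3,
E[sin 2θ] = 2/3 under the sin θ law), not 1 — the doubled-angle resultant
is a circle statistic applied to a folded 3D angle, and we use it only as a
monotone dispersion index.

**Peak estimation.** Two estimators are provided and recorded in every
output: `hist_mode` (center of the most populated bin, ties toward the
lower bin) and the default `kde` — a Gaussian KDE with Silverman bandwidth,
the sample reflected at both domain boundaries so the density is not
depressed at 0° or 90°, evaluated on a 0.1-unit grid. A peak-to-median
density ratio near 1 flags flat distributions whose peak is not meaningful.

**Radial profile.** Polylines are resampled at fixed 2 nm arc spacing
before computing distances to the assembly's spatial center, so densely and
sparsely traced filaments weigh equally. The default center is the
arc-length-weighted centroid of the assembly filaments; a provided-point
override exists for sensitivity checks.

## Distance and exclusion statistics

Nearest-neighbor distances between particles are exact (k-d tree, verified
against the O(n²) scan). Point-to-mask distances are exact Euclidean
distances to the nearest *foreground voxel center* (k-d tree over centers),
with points inside a foreground voxel assigned 0; mask-to-mask distances
evaluate the exact Euclidean distance transform of the target background at
the source voxel centers, where the EDT is exact. Sub-voxel surface
interpolation is deliberately not attempted: half-voxel granularity at the
default 4 nm pitch is negligible against the 25–300 nm signals of
interest. "Contact" defaults to distance exactly 0; a configurable
`contact_threshold` widens it. No edge correction is applied for lamella
truncation; instead, when a threshold is set, query points within one
threshold of a slab face are flagged in the output.

## Shape metrics

Principal axes are eigenvectors of the coordinate covariance of foreground
voxel centers (or 2 nm-resampled polyline points); axis *lengths* are
projection extents (max − min along each axis), sorted L ≥ M ≥ S, because
projection extents match the long/short-axis reading of fluorescence spot
measurements better than eigenvalue multiples. A 2D projection mode
reproduces SIM-style in-plane L/S. Nucleoid width is the median over
one-voxel-thick axial slices of each slice's extent along its own in-plane
principal direction; the median makes it robust to sparse end slices.

## Synthetic scenes

Filaments are discrete worm-like chains (Kratky–Porod): fixed step
ds = 5 nm, successive tangents drawn from a von Mises–Fisher distribution
about the previous tangent with κ = Lp/ds, giving
⟨t(s)·t(s+Δ)⟩ ≈ exp(−Δ/Lp). The vMF cosine uses the closed-form inverse
CDF for dimension 3; κ > 1e12 returns the rigid limit exactly. Confinement
(sphere, ellipsoid, elliptic cylinder with flat caps) acts by specular
reflection — the bounce point becomes a polyline vertex, so step length is
conserved and no boundary density artifact arises, unlike rejection
sampling. The persistence-length estimator resamples chains at ds, computes
the mean tangent autocorrelation by FFT, and fits log C(Δ) = −Δ/Lp through
the origin over the leading lags with C > 0.2; it recovers Lp within 15%
across 50–1000 nm (50 chains × 2000 steps).

Condensate masks derive from the filaments themselves — rasterization at
half-voxel sampling with 2.5 nm radius (the ~5 nm filament width),
morphological closing (ball, 16 nm) to bridge meshwork pores, then dilation
by `condensate_dilation_radius` (12 nm) — because the condensate is
templated by and embedded in the meshwork rather than an independent
ellipsoid. Morphology is computed with exact EDT thresholding inside the
foreground bounding box.

Ribosomes are a hard-core point process by random sequential adsorption:
candidates uniform over domain voxels (jittered within the voxel, so
point-in-mask tests are consistent with the sampling), rejected inside
exclusion masks or within d_hc = 25 nm of an accepted point, with an
attempt budget of 100× the target count ⌈λ·V⌉ (under-filling warns, never
raises). Intensity λ = 1.8×10⁻⁵ /nm³ sits in the physiological range for
bacterial cytoplasm and yields ≳1000 ribosomes per cropped scene.

A whole scene composes: a nucleoid bundle along the cell axis (elliptic
cylinder 900 × 260 × 260 nm, σ = 10° initial dispersion, Lp = 20 µm —
far above the confinement width, so alignment is maintained in the Odijk
deflection regime and the fragment-angle peak stays below ~20°); a
genotype-specific assembly placed beside it (WT: isotropic, Lp = 60 nm,
sphere r = 110 nm, surface gap 10 nm, ribosome exclusion on; dPomZ:
isotropic, Lp = 80 nm, ellipsoid 180 × 105 × 105 nm, gap 40 nm, exclusion
on; dPomY: σ = 15° aligned, Lp = 350 nm, ellipsoid 280 × 95 × 95 nm, gap
65 nm, exclusion off); an analytic membrane shell (cylinder radius 340 nm,
8 nm thick); and a final slab crop to z ∈ [−50, 50] nm with exact
plane-intersection splitting of filaments. All numbers are artifact
choices tuned only to reproduce qualitative contrasts (ordering of
elongation, nucleoid distance, selectivity); they are not measurements, and
nothing downstream assumes them. Every generator is bit-reproducible given
its seed; scene generation derives per-component sub-seeds from one
SeedSequence.

## Statistical comparisons

Angle distributions: two-sample KS on the raw samples, and a seeded
permutation test (default 10⁴ permutations) on |Δ circular spread| with the
(1+k)/(1+N) p-value estimator, which never returns 0 and keeps the test
level-valid at any permutation count. Both are reported when no method is
named, since the right test for axial data is genuinely open. Calibration
on simulated nulls (isotropic angle samples against a known axis) puts both
tests' type-I error at 0.05 ± 0.02. One caveat found during calibration:
when each sample's angles are measured against its *own fitted* mean axis,
the KS test becomes strongly conservative (the fit shrinks each empirical
distribution toward the population law — the Lilliefors effect); p-values
between groups fitted separately are therefore conservative, not inflated.

Scalar metrics use one-way fixed-effects ANOVA (zero-variance equal-mean
groups give p = 1 by convention); per-replicate means are attached when
replicate labels are provided. No multiple-testing correction is applied by
default; a Holm adjustment can be applied downstream to the tidy p-value
tables.

## Pipeline and provenance

`RunConfig` is the single source of analysis parameters; its SHA-256 short
hash is embedded in every output table, and `compare` refuses to pool
results with differing hashes. CLI reruns with fixed seeds are
byte-identical; wall time and versions go to stderr only. Default problem
sizes (50,000 vectors for isotropy checks, 50 × 2000-step chains for Lp
recovery, 10 seeds per genotype for ordering checks, ~10⁶-voxel grids) keep
a full simulate→analyze→compare sweep of all genotypes in minutes on one
CPU.

## What the synthetic data does and does not show

The generator reproduces the geometry the analysis assumes — isotropic vs
aligned axial statistics, hard-core exclusion, preset size/gap orderings,
lamella truncation — so passing tests demonstrate that the estimators
recover known ground truth under those conditions. It does not emulate
tracing errors (broken or merged centerlines), anisotropic missing-wedge
artifacts, template-matching false positives, curved cell geometry, or
condensate wetting physics; conclusions about robustness to those effects
cannot be drawn from these tests. Mask-based distances carry half-voxel
granularity; filament-width estimation from density is out of scope (width
is a generator parameter here).
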