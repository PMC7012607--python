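# Methods

## Scope and model

`notomorph` quantifies the hydrostatic-scaffold role of the notochord
during zebrafish spine formation through five measurement families:
vacuolated-cell shape, nuclear radial distribution, per-centrum
deformation symmetry, vertebral canal size, and spine kink geometry. All
measurements operate in physical units (µm) on voxel grids indexed
`(ap, dv, lr)` — anteroposterior, dorsoventral, left-right — with voxel
centers at integer indices and physical coordinate = index × spacing.
AP is axis 0 everywhere.

## Synthetic data generator

The generator produces the study conditions every other module is tested
against. It emulates:

* **Tube and cells.** A cylindrical notochord (default 800 µm long,
  40 µm radius) filled with `n_cells` (default 40) ovoid cells on a
  jittered staircase lattice: consecutive cells alternate dorsal/ventral
  offsets (±0.45 R) so they interdigitate, as intact vacuolated cells do.
  Each cell is a spheroid with radial semi-axes 0.52 R and an AP semi-axis
  set by its target volume. Cells are rasterized 5% oversized, overlaps
  are resolved by nearest seed in the per-cell normalized ellipsoid
  metric (a Voronoi rule restricted to the tube), and each cell is then
  trimmed back to exactly its target voxel count, outermost voxels first.
  The trim makes realized volumes track the generating pattern to within
  one voxel, so rank statistics on measured volumes are exact. If the
  requested volumes cannot fit at the requested count, generation fails
  with an explicit packing error rather than silently truncating.
* **AP volume pattern.** Target volumes follow
  `baseline + amplitude · sin(2π·ap/period)` (defaults 27 000 ± 5 000 µm³,
  period 317 µm). The period is deliberately non-commensurate with the
  default 20 µm cell pitch so the sampled pattern values are pairwise
  distinct; a period that divides the pitch evenly (e.g. 300 µm) produces
  exactly repeated values and rank correlation with the pattern could
  never be exactly 1. `randomized` mode shuffles the same values along
  the axis, emulating the loss of the stereotyped pattern.
* **Fragmentation.** A configurable fraction of cells (mutant default
  0.5) is split into k fragments (default 4) by internal Voronoi seeds;
  each fragment is eroded toward its seed to a configurable volume
  retention (default 0.7), so the per-parent fragment volume sum is
  exact by construction.
* **Nuclei.** One nucleus per parent cell, default volume 400 µm³
  (≈ 9 µm diameter, typical of larval notochord nuclei). Mode
  `peripheral_disc`: an oblate spheroid (axis ratio 1:4, short axis
  radial) tangent to the cell boundary farthest from the tube axis —
  the shape and position of a nucleus squeezed by an inflated vacuole.
  Mode `central_sphere`: a sphere at the cell centroid — the collapsed-
  pressure phenotype.
* **Imaging.** Membrane channel: 200 on label boundaries, 10 in cell
  interiors, 0 outside; nucleus channel: 200 inside nuclei. Isotropic
  Gaussian blur (σ in µm) then additive Gaussian noise. No PSF
  anisotropy or depth attenuation is modelled: the imaging model exists
  to stress segmentation, not to simulate microscopy. Consequently,
  passing tests demonstrate correctness of the measurement chain on
  geometry like the real tissue's, not robustness to all real-microscopy
  artifacts (scatter, bleaching, sheath autofluorescence).
* **Sagittal profiles and kinks.** Dorsal/ventral contours at
  ±R, indented under each centrum by an arc of exactly the configured
  circle radius over the central 70% of the centrum span; an indentation
  deeper than the tube radius is rejected. Kinks are injected by
  rotating the posterior part of the centerline about the kink point, so
  the interior angle is exact and arc length is preserved exactly.

Determinism: everything derives from one `numpy` generator seeded by
`config.seed`; identical config + seed gives bit-identical arrays.

## Segmentation

Classical watershed chain, anisotropy-aware and deterministic: Gaussian
smoothing (σ in µm), Otsu threshold → membrane mask, hole-filling →
tube region, tube minus membrane → interiors, Euclidean distance
transform in µm, h-maxima seeds (default h = 2 µm), seeded watershed on
the inverted distance over the tube (so membrane voxels are assigned to
the adjacent cell), then a minimum-volume filter (default 50 µm³;
benchmarks in this repository use 500 µm³, well below the smallest
generated cell). Every step is invariant to positive intensity scaling.
Watershed flooding ties are resolved by the fixed voxel scan order.
Matching against reference labels is greedy one-to-one by descending
IoU with deterministic tie-breaks.

## Shape metrics

Volume is the voxel count × voxel volume. Surface area comes from a
watertight marching-cubes mesh of the padded binary mask, smoothed with
**Taubin's shape-preserving mesh filter** (20 iterations). The raw
staircase mesh overestimates the area of digitized smooth objects by up
to tens of percent (biasing sphericity low); smoothing the *image*
instead of the mesh removes the staircase but shrinks objects only a few
voxels across (biasing small-nucleus sphericity above 1). Taubin
smoothing measured: digitized sphere Ψ = 0.992, unit cube 0.817 (closed
form 0.806), 2:1 prolate spheroid 0.921 (closed form 0.929), 4:1 oblate
disc 0.706 (closed form 0.701) — all within the ±0.02 tolerance used
throughout. Sphericity is Ψ = π¹ᐟ³(6V)²ᐟ³/A, ≤ 1 by the isoperimetric
inequality up to mesh tolerance.

Notochord length is the occupied AP extent of the labelled cells — valid
for straight specimens; kinked specimens should use the centerline arc
length from the kink module instead. The AP volume-profile dissimilarity
is the L1 distance after normalizing AP to [0, 1] and interpolating to a
common grid; volumes are deliberately not normalized, so a uniform
volume change is detected.

## Nuclear statistics

ρ is computed in the notochord cross-section at the nucleus centroid's
AP slice; the local radius is the equivalent-circle radius of that
cross-section (robust to mild non-circularity), and the local axis is
the cross-section centroid. A single-section (histology) mask is the
same computation with an AP extent of one voxel. The peripherality test
compares the empirical CDF of ρ with the uniform-in-disk null
F(x) = x² by the sup-distance D, with an exact Monte-Carlo p-value
p = (1 + #{D* ≥ D})/(n_null + 1). The null operationalizes "randomized
localization"; both peripheral clustering (wild-type-like) and central
clustering (mutant-like) reject it, in opposite tails of mean ρ.

## Deformation and symmetry indices

Circles are fitted by the algebraic (Kåsa) least-squares method — linear,
deterministic, exact on noiseless arcs; radius bias at realistic noise is
below 1%. Collinear points return an infinite-radius sentinel rather
than an error. Per centrum, each side's contour is restricted to the
central 60% of the centrum span (a config knob; the flared ends near the
prospective intervertebral disc are excluded). A side is scored as an
indentation only when it bows toward the midline and its fitted radius
is below 10× the notochord radius; otherwise it is flat (+∞).

The index D = −min(r_d, r_v)/max(r_d, r_v) is a convention chosen so
that D = −1 iff both radii are finite and equal (symmetric compression),
D → 0 as one side flattens, and D is unitless; the published cartoon of
the index constrains only these properties, not the formula. The signed
asymmetry A = (r_v − r_d)/(r_v + r_d) is antisymmetric under swapping
the sides; its limits give A = +1 when only the dorsal side indents
(r_v = ∞), A = −1 when only the ventral side does, and A = 0 when both
are flat. The vertebral symmetry index is the identical computation on
the outer dorsal/ventral contours of a centrum's bone outline.

Canal diameter: in the cross-section at the AP midpoint of a vertebra,
the canal is the largest background component enclosed by bone;
diameter = 2√(area/π). Resolution limits accuracy to about ±2 voxels of
spacing.

## Kinks and colocalization

Centerlines come from per-AP-slice centroids of a single connected
region, lightly smoothed (5-slice moving average). The kink angle at an
arc-length position is the interior angle between two total-least-squares
lines fitted over a window (default 150 µm ≈ one centrum length — the
published measurements drew the flanking lines by hand, so the window is
a free parameter) on either side: 180° = straight, invariant to rigid
transforms and to orientation reversal because positions are arc-length
positions. Detection takes local minima of the sliding angle profile
below a threshold, non-maximum-suppressed within one window.

The colocalization statistic is the mean distance, in centrum counts,
from each kink (mapped to its nearest inter-centrum boundary) to the
nearest flip in the sign of A. The null re-places kinks independently
and uniformly among boundaries; p = (1 + #{null ≤ observed})/(n_perm+1)
is exactly valid. Because the statistic is discrete, the test is
conservative on short axes (on a 30-centrum axis with 2 kinks the
attainable rejection rate at α = 0.05 is ≈ 0.026); calibration checks
therefore use a 60-centrum axis, where the attainable p-values are dense
enough for the nominal rate to be reached. This is a property of any
exact discrete test, not an implementation artifact.

## Problem sizes and numerical choices

The reference specimen (40 cells, 800 µm × 40 µm tube at (2, 1, 1) µm
spacing, ≈ 3.2 M voxels) generates in under a second and segments in a
few seconds; multi-seed sweeps use a 12-cell, 240 µm variant with the
same geometry rules. Monte-Carlo calibrations use 199 null draws per
replicate × 1000 replicates; reported p-values in single analyses use
9999 draws. Tolerances: sphericity ±0.02 (mesh), circle fits 1e-9 on
noiseless data, kink angles ±0.5° (±2° after detection on resampled
profiles), radii ±5% in parameter recovery. Degenerate inputs are
explicit: empty images segment to zero instances with a warning,
collinear contours give flat sentinels, absent asymmetry flips give
p = 1 with an infinite-distance sentinel, missing voxel spacing on TIFF
input is an error rather than a silent default.

## Known limitations

* The staircase lattice is a geometric stand-in for the published cell
  arrangement patterns, not a re-implementation of that classification.
* Sphericity of objects only 2–3 voxels thick is biased even with mesh
  smoothing; nuclear shape comparisons should use ≤ 1 µm spacing.
* Stage/genotype are free-text group labels; nothing is inferred from
  the images.
* No mechanical simulation of pressure or bone growth: the generator
  reproduces the *geometry* of the phenotypes, not their dynamics; no
  µCT-specific processing (ring artifacts, beam hardening, density).
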