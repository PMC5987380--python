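# Methods

## Scope and data model

Volumes are `(z, y, x)` arrays with isotropic voxels; `z` is proximodistal
with the proximal end at `z = 0`, and all percent-of-length positions are
measured from the proximal end.  Connectivity is fixed package-wide:
26-connectivity in 3D, 8-connectivity in 2D.  Stacks are stored as
multi-page TIFF with a JSON sidecar carrying the voxel size in microns; a
stack without a stated voxel size is rejected rather than defaulted,
because every geometric output scales with it.

## The phantom generator

The phantom emulates a murine tibia as the measurement chain sees one: a
hollow shaft of elliptical cross-section whose semi-axes, wall thickness
and ellipticity vary along the bone, a centroid that follows a circular
arc, an optional parallel fibula rod, an optional metaphyseal trabecular
lattice, and two calibration rods of known attenuation outside the bone.

**Wall models.**  Three inner-boundary models are provided.  `axis`
(inner semi-axes `a−t, b−t`) and `scaled` (inner `= k·outer`,
`k = (b−t)/b`) have elementary closed forms for area and second moments;
the `scaled` model additionally makes the section's `I_max/I_min` equal
the squared axis ratio exactly, which is why cohort phantoms use it — an
injected ellipticity shift propagates to the measured quantity without
approximation.  `offset` defines the inner boundary as the inward parallel
curve of the outer ellipse at distance `t`, giving a wall of constant
normal thickness; its area follows from the ellipse perimeter
(`t·P − πt²`) and its second moments are evaluated by Green's-theorem line
integrals over the analytic curve with a periodic trapezoid rule, which is
spectrally accurate and serves as the machine-precision oracle for the
voxel measurements.  The offset curve is regular only below the minimum
radius of curvature (`t < b²/a`); thicker walls are rejected.

**Voxelization** is centre-point inclusion with no anti-aliasing, so the
binary volume is an exact predicate of the continuous geometry;
the grayscale volume adds a one-voxel Gaussian blur (partial volume), the
calibration rods, and optional Gaussian noise.  Analytic ground truth is
always computed from the continuous specification, never from voxels —
with one deliberate exception: trabecular bone volume fraction, where the
realized voxel count on the phantom grid *is* the ground truth.

**Curvature** is a one-parameter circular arc in a configurable plane,
quantified by the sagitta (maximum perpendicular deviation from the chord,
attained at midshaft).  One parameter matches the single lever-arm
statistic the analysis produces.

**Trabecular region.**  A periodic lattice (rods, plates, or solid with
spherical voids for the isotropic control) is clipped to the medullary
envelope — the cavity interior eroded by four voxels so that the lattice
never fuses with the cortex even after blur-plus-threshold dilation.  Two
in-plane islands, each held 26-connected by a thin longitudinal spine, are
separated by a gap and joined only by a bridge plate (as thick as one
trabecular element, so it survives thresholding) at a prescribed slice:
that slice is the recorded ground truth for the reference-finding
landmark.  Because primary-spongiosa islands in real metaphyses are
connected structures, the spine is a modelling convenience, not an attempt
at biological realism.

**Cohorts.**  A full 2 × 2 × 3 factorial (genotype × sex × age; n = 5 per
cell by default, 60 animals) is materialized from a flat baseline
parameter dict; effects are cell-conditional additive/multiplicative
shifts (a one-factor condition encodes a main effect, a multi-factor
condition an interaction-bearing cell shift), and per-animal Gaussian
parameter noise models biological variation.  This makes the dominant
noise *animal-level*, i.e. strongly correlated across sites along the same
bone — the realistic regime, and the one under which contiguous
significant regions are the meaningful readout.  Small independent
per-site measurement noise can be added on top.  One master seed is split
into per-animal substreams (`numpy` `SeedSequence`) and recorded in the
covariate table; identical seeds reproduce cohorts bit for bit.  No
quantitative effect sizes are prescribed by the source material for shape
differences, so cohort effect magnitudes are user parameters; the demo
uses a +0.3 ellipticity shift at 30–40 % of length for one genotype–sex
cell with animal-level ellipticity noise of 0.05.

## Preprocessing

**Thresholding** is a global minimum threshold (`value ≥ thr`), with Otsu's
method available as a suggestion and a despeckle step (drop 3D components
under 50 voxels) as standard post-threshold cleanup.

**Fibula removal** tracks the tibial component through per-slice
8-connected labelling, choosing the component with maximal overlap with
the previous tibial slice (nearest centroid as fallback).  Components
interior to the filled tibial silhouette are intramedullary bone and are
kept; exterior components are fibula candidates.  When a tracked exterior
component fuses with the tibia (detected by its tracked centroid falling
inside the merged component together with an area jump), the slice is
split by a watershed on the distance transform seeded at the two tracked
centroids, and the affected slices are logged.  Fusion handling is a
package decision — deterministic and auditable — since no standard exists.

**Alignment** rotates the principal inertia axis of the voxel cloud onto
`z` (or a landmark chord in landmark mode), resampling binary masks
nearest-neighbour so voxel counts are conserved to within resampling
tolerance; rotations under 0.1° are skipped so already-aligned data passes
through untouched.  An almost-isotropic voxel cloud (largest eigenvalue
less than twice the second) has no meaningful axis and is rejected.

**Trabecular ROI anchoring.**  Per slice, the cortical shell is the union
of 2D components touching the outer boundary of the filled silhouette; the
interior envelope is the shell's filled interior minus the shell.  The
reference slice is the most proximal `k` such that the intramedullary bone
in slices `[0, k]` forms a single 26-connected component (components under
27 voxels ignored), found by bisection — on the phantom this recovers the
bridge slice exactly or within one slice after thresholding.  The ROI then
spans `round(0.05 × total slices)` slices distal of the reference, and the
trabecular mask is bone ∩ envelope.

## Morphometry conventions

* **Second moments** include the per-pixel self term `s⁴/12` per axis so
  small sections are not underestimated.  `J = I_min + I_max` is the polar
  moment ("predicted resistance to torsion"); the true torsional constant
  of non-circular sections is explicitly out of scope.  Ellipticity is
  `I_max/I_min` by default (`axis_ratio` gives its square root).
* **Local thickness** is the sphere-fitting distance-ridge transform.  The
  phase boundary is taken halfway between foreground and background voxel
  centres, so diameters are `2·EDT − 1` voxels and an isolated voxel has
  thickness 1.  Accuracy floor: about one voxel (parity and surface
  digitization), hence wall/trabecula thicknesses should span at least
  4 voxels (enforced by the phantom spec) and percent-level accuracy
  claims require several tens of voxels, which is how the geometry
  validation suite is sized.
* **Ct.Th** is measured per slice in 2D (inscribed disc), consistent with
  reporting at each percent of length; 3D local thickness remains
  available through the trabecular module.
* **Tb.N** uses the direct model `(BV/TV)/Tb.Th`.  Tb.Sp is reported in
  mm (it is a length; the inverse-millimetre unit sometimes printed for
  separation in summary tables is treated as a typographical artefact).
* **MIL/DA**: deterministic Fibonacci-hemisphere directions (512 by
  default; validation suites use 128 for runtime) with a parallel-line
  raster per direction, trilinear sampling thresholded at 0.5 (suppresses
  spurious crossings from jagged voxel surfaces on oblique lines), and an
  optional VOI restricting the analysis (a central sphere for
  rotation-invariance studies; the ROI envelope in production).  The
  fabric tensor solves `ωᵀHω = MIL⁻²` by least squares.  Ideal plates give
  a legitimately rank-deficient fabric, so small negative eigenvalues
  (within 20 % of `λ_max`, fit noise) are clamped to zero; genuinely
  indefinite fits raise with diagnostics.  `DA = 1 − λ_min/λ_max` in
  `[0, 1]` by default; the `λ_max/λ_min` ratio convention is a flag.
* **TMD / cortical BMD** are one quantity: mean calibrated density over
  cortical voxels in 100 slices centred at the 37 % site (the site is
  stated without centring convention anywhere authoritative; centring is
  the package's documented choice).  The attenuation→density map is linear
  through the two calibration-rod pairs.
* **Porosity** fills the outer contour per slice, excludes the medullary
  cavity (largest enclosed background component), and reports
  pore/shell voxel percentages; slices with a breached shell are flagged
  and underestimate porosity.
* **Moment arm** uses the chord through the centroids of the most proximal
  and most distal nonempty slices (landmark-axis mode covers replication
  of axis-based loading setups).  Arms below 10⁻¹⁰ mm are snapped to zero
  so a straight bone reports exactly zero.  The lever-arm normalization
  divides by the area-equivalent outer radius `√(filled/π)`; "radius" is
  undefined for non-circular sections, and the semi-major-axis alternative
  is available behind a flag.
* **Beam surrogate**: `σ = P/CSA + P·arm·c/I` with `c` the equivalent
  outer radius and `I = I_min` (conservative).  It is labelled a
  beam-theory surrogate in its output metadata; it is not a finite-element
  result and is provided only to rank sections under combined compression
  and curvature-induced bending.

## Statistics

The factorial model is fitted by least squares on a sum-to-zero contrast
design; each of the seven effects is tested by the Type III principle
(refit without that effect's columns, F-test on the SSE increase).  For
the balanced designs the generator produces, Type I and Type III coincide,
and on unbalanced data the implementation agrees with
`statsmodels.anova_lm(typ=3)` to machine precision (verified in the test
suite — the implementation is vectorized over responses so an 81-site map
or 1000 simulated replicates is one linear-algebra call).  Constant
responses are flagged degenerate (`p = NaN`, `R² = 0`).  Age is a
three-level categorical factor.  Shapiro–Wilk (residual normality) and
Bartlett (variance homogeneity across the 12 cells) are screens: warnings
are recorded and the analysis proceeds.  Group summaries are cell means
with t-based 95 % CIs (n−1 df).  No multiplicity adjustment is applied
across the 81 sites by default — wide contiguous bands are the
interpretive unit — with per-effect Benjamini–Hochberg available as a
flag.  Heatmap rendering is deterministic (fixed layout and colours), so
figures are hash-comparable.

## Validation suites and problem sizes

All validation runs on synthetic data generated at call time:

* *Geometry*: 20 randomized offset-wall rings at 12.5 µm pixels (semi-minor
  ≥ 100 px, walls ≥ 60 px — sized so the one-voxel thickness floor stays
  under the 2 % claim); worst-case errors vs the quadrature oracle, exact
  `J` identity, re-voxelized rotation invariance.
* *Trabecular*: 64³ lattices at 50 µm; BV/TV equality with generator
  counts is exact by construction of both paths sharing one grid; plate
  thickness/separation against whole-layer analytic values; DA ordering
  plates > rods > isotropic and 30°-rotation invariance inside a spherical
  VOI.
* *Curvature*: arc phantoms (8 mm bone, 25 µm voxels) across sagittas
  0–0.5 mm.
* *Type-I error*: 1000 Gaussian null cohorts on the 2×2×3, n = 5 layout;
  empirical per-effect rejection at α = 0.05.  The per-seed rate is
  Binomial(1000, 0.05), so individual runs scatter by a few per mille
  around 5 %.
* *Localized effect*: the demo cohort's interaction recovery, counting
  non-blue interaction bands inside 30–40 % and blue bands outside.
* *Determinism*: the demo pipeline run twice; CSV/JSON outputs hashed.

The demo bone itself is scaled down (12 mm length at 40 µm voxels) relative
to a real tibia scan; the phantom geometry scales freely and the voxel
size is a parameter, so the same code runs unchanged at 5 µm.

## What the phantoms do and do not show

Passing the oracle suites demonstrates that the measurement chain is
correct on geometry it can represent exactly: smooth elliptical cortices,
periodic lattices, circular-arc curvature, Gaussian noise.  Real scans add
beam hardening, ring artefacts, partially mineralized surfaces, irregular
trabecular architecture and growth-plate structures that the generator
deliberately does not model; threshold choice on real data remains a
user decision (it is a required parameter, never defaulted), and the
fused-fibula watershed split should be audited via its logged slice range
on any real dataset.

## Known limitations

* Inscribed-sphere thickness carries the one-voxel floor described above.
* DA for near-degenerate (plate-like) fabrics saturates at 1 and its
  principal-direction estimate is direction-grid limited (~1–2° at 128
  directions); strongly oblique rod lattices can deviate up to ~0.07 in
  DA from their axis-aligned equivalents at that direction count.
* The beam surrogate ignores transverse shear, section warping and
  material heterogeneity by design.
* `total_porosity` cannot see pores connected to the endosteal surface in
  the same slice (they merge with the cavity); a breached cortical shell
  is flagged rather than repaired.
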