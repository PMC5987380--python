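# bonemap

Whole-bone micro-CT morphometry for rodent long bones: trabecular
architecture in a landmark-anchored metaphyseal region, cortical slice
geometry profiled along the entire shaft, curvature lever-arm statistics,
and site-matched three-way factorial significance maps — together with a
synthetic tibia phantom generator that provides analytic ground truth for
every measurement, so the whole chain is testable without scan data.

## Who this is for

Skeletal-phenotyping studies increasingly compare bone *shape* along the
entire bone rather than at a single site: cross-sectional area, principal
second moments, ellipticity and curvature are evaluated at every percent of
bone length and compared across experimental groups (e.g. genotype × sex ×
age cohorts of mice), with significance rendered as banded heatmaps along
the bone axis.  `bonemap` implements that workflow end to end on standard
multi-page TIFF stacks and provides a first-class phantom module for
validating each stage.

## The measurements

For a binary cross-section with pixel area `s²`, second moments about the
centroid are computed from pixel coordinates with the per-pixel self term
`s⁴/12`:

    Iₓ = Σ (y−ȳ)² s² + n s⁴/12,   I_y = Σ (x−x̄)² s² + n s⁴/12

Eigen-decomposition gives the principal moments `I_min ≤ I_max`; the polar
moment `J = I_min + I_max` serves as predicted resistance to torsion, and
ellipticity is `I_max / I_min`.  Mean cortical thickness (Ct.Th) is the
mean 2D inscribed-disc diameter; trabecular thickness and separation use
the same sphere-fitting local-thickness transform in 3D.  Degree of
anisotropy comes from a mean-intercept-length (MIL) fabric tensor `H`
fitted to `MIL⁻²(ω) = ωᵀHω` over quasi-uniform directions, with
`DA = 1 − λ_min/λ_max` (0 = isotropic).  Tb.N uses the direct model
`(BV/TV)/Tb.Th`.

Curvature is summarized by the moment arm: the perpendicular distance from
each slice centroid to the proximal–distal chord, and the dimensionless
curvature lever arm = midshaft arm / area-equivalent outer radius.

At every percent of length a three-way factorial linear model
(genotype × sex × age, Type III tests with sum-to-zero contrasts) yields
seven p-values (3 main effects, 3 two-way, 1 three-way) mapped to colour
bands: red `P < 0.001`, yellow `0.001 ≤ P < 0.01`, green `0.01 ≤ P < 0.05`,
blue `P ≥ 0.05`, plus model R² and per-cell mean ± 95 % CI.

## Worked example

Regenerate the synthetic demonstration (a curved, fibula-bearing tibia
phantom through the full image pipeline, plus a 60-animal factorial cohort
with a localized genotype×sex ellipticity interaction):

```sh
bonemap reproduce-demo --seed 0 --out demo/
```

`demo/demo_bone_summary.json` reports, among others:

```json
{
  "curvature_lever_arm": 0.4964,
  "true_lever_arm": 0.5039,
  "trabecular_bridge_truth": 21,
  "trabecular_ref_found": 21
}
```

The measured curvature lever arm (0.496) recovers the phantom's analytic
value (0.504) to ~1.5 %, and the trabecular "bridge" reference slice — the
slice where the two primary-spongiosa islands first connect, which anchors
the trabecular ROI — is found exactly (slice 21).  In `demo/statmap.csv`
the injected genotype×sex ellipticity interaction at 30–40 % of length
shows as 11 consecutive red bands inside the window (model R² ≈ 0.89 at
35 %) with blue bands almost everywhere else — the site-matched map
localizes the effect it was given and stays quiet where there is none.

The same stages are scriptable individually (`simulate`, `preprocess`,
`trabecular`, `cortical`, `shapeload`, `statmap`) or callable as library
functions (`bonemap.phantom`, `bonemap.volio`, `bonemap.trabecular`,
`bonemap.cortical`, `bonemap.shapeload`, `bonemap.statmap`).

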