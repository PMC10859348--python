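# Methods

## The parametric model

A mid-modiolar cross-section of the cochlear duct is described by nine
boundary landmarks on the bony canal wall and sixteen internal
parameters, each a fitted function of the cochlear angle θ (degrees
along the spiral, 0 at the most basal section, two full turns = 720°).
Four curve families occur:

| family      | form                           | parameters |
|-------------|--------------------------------|-----------|
| Gaussian    | a·exp(−c(θ−b)²) + d            | α, Wa, Wm, Wd, Hkm |
| exponential | a·exp(bθ) + c                  | Fv, Wsl, φ_fm, Hkn, φ_en |
| cubic (centred) | polynomial in θn = (θ−c1)/c2 | Hsg, Ft, Wc, β |
| linear      | mθ + q                         | Bm, Wsm |

All length-like parameters are dimensionless fractions of the **basal
canal width** (distance from LS to the midpoint of MSVS and MSTS of the
most basal section); α and β are angles in radians. The radian reading
of the α curve (0.098–0.212 rad ≈ 5.6–12.1°) is the only one consistent
with the 0–15° range quoted for the measured data, and all public
interfaces convert explicitly when degrees are requested. Coefficients
are stored to full published precision. Angles beyond 720° are permitted
only behind an explicit extrapolation flag (with a warning), since the
curves are unconstrained beyond the fitted range.

## Landmark construction

Construction happens in a local frame derived from the boundary
landmarks themselves (origin LS, +x toward the MSVS/MSTS midpoint, +y
toward SS), which makes the pipeline equivariant under rigid motion,
mirroring and uniform scaling — properties the test suite asserts to
1e−9. The canal wall between the nine landmarks is interpolated with a
closed periodic C1 cubic spline in a chord-length parameter (the source
material does not specify the interpolant); intersection queries bracket
on a 512-point sampling and refine by bisection on the spline to 1e−12
of the curve parameter.

The construction order is: a (wall point at vertical offset Wa from
LS) → the lamina line through a at angle α → g (medial wall crossing) →
k = a + Wsl·û (ligament/membrane junction) → h (organ of Corti, Wm from
LS along the line) → i = h + Hsg·n̂ (lamina thickness) → o, p (lamina
extents at chord distances Ft/Fv from a along the tympanic/vestibular
band edges) → c, d (ligament/wall crossings at horizontal offsets
Wc/Wd) → e, f (ligament mid-points) → l (membrane root, Wsm medial of i
on the vestibular band edge) → b (Reissner's membrane endpoint).

Three constructive choices deserve note:

- **Lamina extents.** The lamina band runs medially from h/i; o and p
  are placed at the chord distances Ft and Fv on its two edges. Since
  Ft ≈ 0.76 canal widths while the medial wall sits at ≈ 1.0 widths,
  the strip between o/p and the wall is emitted as a *modiolar bone*
  wedge. This both resolves an over-determined landmark definition and
  gives Ft/Fv a physical role: they set the split between conductive
  nerve tissue (σ = 0.33 S/m) and resistive bone (0.016 S/m) along the
  lamina, which the sensitivity analysis probes. If a chord distance
  would overshoot the wall it is clipped with a warning.
- **Ligament mid-points.** e and f are placed from the chords k–c and
  k–d by an along-chord component (Hkn, Hkm) and a lateral perpendicular
  offset (φ_en, φ_fm). Taken literally, the fitted offsets (up to 0.6
  canal widths) would push the points outside any plausible canal, so
  the along-chord component is capped at 75 % of the chord and the
  lateral offset at 50 % of the free distance to the wall, shrinking
  further if the resulting quartic still leaves the canal. Every cap is
  reported as a warning; zero-offset inputs are untouched. The quartic
  Bézier through each triple interpolates its mid-landmark exactly at
  t = 0.5 (inner control points blended halfway toward the landmark,
  the central control point solved from the interpolation constraint).
- **Reissner's membrane.** The membrane is cast from l up-laterally
  (direction rotated by π − β from the lamina direction) and b is the
  first hit on the chain [ligament curve k→c, then the wall medially
  from c]. Basal sections intersect the ligament curve; apical sections,
  where the ligament boundary sits lateral of l, terminate on the wall —
  both give valid region decompositions. Grazing intersections are
  snapped onto the exact curve parameter so curve splits at b are
  consistent.

The assembled cross-section comprises six simple, pairwise-disjoint
regions (scala tympani/media/vestibuli, spiral ligament, lamina nerve
channel, modiolar-bone wedge) and four thin layers treated as contact
impedances with their conductivity/thickness defaults: temporal-bone
lining (0.0334 S/m, 0.02 mm) around the canal and along both lamina
plates, basilar membrane (0.0126, 0.005) on the path a→k→h, Reissner's
membrane (0.0001, 0.002) on l→b, and stria vascularis (0.005, 0.01) on
the scala-media lateral wall. Curved boundaries are sampled at ≈ 1/48 of
the canal width so adjacent regions and the lining share vertices
exactly.

## Template-morphing baseline

The baseline normalises a generalised internal geometry into the box
spanned by IS, LS, SS and the MSVS/MSTS midpoint and fits it to a target
section by anisotropic scaling, translation, and an optional mirror
flip. Anisotropic (per-axis) scaling was chosen over uniform scaling
because the target box is generally non-square; the morph is affine, so
collinearity and length ratios are preserved. The shipped default
template is the parametric construction at θ = 0 on the canonical
synthetic boundary, stored as a versioned JSON fixture and labelled
synthetic — the original histologic template is not published.

## Validation statistics

The landmark RMSE is implemented verbatim in its published product form
`sqrt(Σ |Δx·Δy| / n)`. This form is insensitive to error confined to a
single axis (a pair with Δx = 0 contributes nothing regardless of Δy);
that property is documented and asserted, and a conventional Euclidean
mode is available behind a flag but never the default. Method
comparison pairs the two methods' per-landmark RMSE values within each
turn and applies the paired two-tailed t-test (scipy), which reproduces
the published p-value row of the reference table — 0.0188, 0.0012 and
0.0067 at 180°/360°/540° exactly to printed precision, and 0.3648 at 0°
against a printed 0.3656 (the published statistic was evidently computed
from unrounded errors; no test variant reproduces it from the rounded
table). An unpaired variant is available behind a flag. The two-way
ANOVA uses Type-II sums of squares (statsmodels) so unbalanced layouts
are handled; layouts without replication automatically drop the
interaction term.

## Equation re-derivation

The outlier rule is interpreted as a *residual* window: residuals from a
preliminary robust (Theil–Sen) straight-line fit outside the inclusive
[P20, P80] window are removed (a raw-value window would delete the
legitimate extremes of angle-dependent trends; it remains available as a
mode). Candidate families are polynomials of order 1–4 (fitted in the
centred variable (x−mean)/std), one- and two-term exponentials, and the
four-parameter Gaussian; nonlinear fits use moment-based initial
guesses with five seeded starts (the two-term exponential additionally
seeds from the one-term solution) and flag non-convergence rather than
failing silently. Selection takes the lowest RMSE, with ties within
1e−8 resolved toward fewer parameters so exactly-nested families at
zero noise resolve to the generating family. Rotation alignment grid
searches the rotation offset over ±15° and refines with bounded Brent on
the straight-line-fit residual of α versus θ.

Recovery behaviour (asserted by the tests at n = 27 sections and 5 %
relative noise): amplitude, rate, centre and width parameters recover
within 10 % relative; the additive offsets of the Gaussian and
exponential families are judged at 10 % of the curve amplitude instead,
because their true values sit at or near zero and a relative error on a
near-zero quantity is ill-posed at that noise level.

## Volume-conduction FEM

The conduction problem is purely resistive: ∇·(σ∇V) = 0 with per-region
conductivities (scala fluids 1.43 S/m, scala media and ligament 1.67,
nerve 0.33, modiolar/temporal bone 0.016, electrode silicone 1e−7).
Thin membranes enter as contact impedances: mesh nodes interior to an
interface polyline carry duplicated degrees of freedom and the weak form
adds a surface-conductance coupling (1/r_s per unit length,
r_s = thickness/σ), so the potential jumps by r_s·J_n across the layer.
Open interfaces whose endpoints meet the domain boundary are sealed by a
half-plane endpoint split so no current short-circuits around the
membrane's end. The source is a uniform inward current density along
the electrode's modiolar-facing arc integrating to 2 mA; the lower
domain boundary is the V = 0 reference. Assembly is standard P1 on
triangles (SI units internally; geometry in mm), solved with a direct
sparse factorisation. Verified against closed forms: the uniform slab
matches the 1D solution and the contact-impedance jump matches the
series-resistance formula to machine precision on aligned meshes; the
ground current balances the source exactly; the solution is linear in
the source current.

Meshing is an in-package conforming-Delaunay scheme: constraint
polylines (region boundaries, interfaces, source arcs) are resampled at
the local target edge length, segments are split at incident vertices so
overlapping collinear constraints share their subdivisions, interior
points come from per-region hexagonal lattices, and missing constraint
edges are recovered by midpoint insertion.

The sensitivity domain is a mid-modiolar half-section: cross-sections at
θ = 0°, 180°, 360°, 540°, 720° (canonical synthetic boundary, basal
width 2 mm, per-turn width decay 0.85) stacked along the modiolar axis,
a 1 mm-wide nerve trunk medial of them running to the grounded lower
boundary, a 0.2 mm-radius electrode contact in the basal scala tympani,
all embedded in a bone-filled square four cochlea-widths on a side. One
fibre path per section runs from the organ of Corti through the lamina
channel into the trunk and down to the level of the most inferior point
of the basal turn, sampled at 200 arc-length stations. Default mesh
sizes are 0.16 mm inside the canals, 0.35 mm in the trunk and 1 mm in
the surrounding bone (≈ 3 700 triangles, ≈ 1.2 s per solve); a
`mesh_scale` knob refines uniformly.

A sweep pins one parameter to each of five values spanning its range and
rebuilds and re-solves the domain per value. Default ranges emulate the
20th–80th percentile window of the original measurements: the 20th–80th
percentile of the fitted curve's own values over θ ∈ [0, 720] stands in
for the unpublished raw data, with two anatomically anchored overrides —
α sweeps 0–15° and Wm sweeps from just above Wsl (a 5 % margin, since
Wm = Wsl collapses the scala media) up to 0.6 mm. A ±20 % mode is also
available. Sweep values whose geometry degenerates (e.g. the Wm floor)
are skipped with a warning and recorded on the result. Parameters are
ranked by the largest potential spread across the sweep at the
worst-case station of the three basal fibres; the two apical fibres are
excluded from the ranking. Under these defaults the lamina
location/size parameters (Wa, Hsg, α, Wm, Ft) each dominate every
ligament/membrane shape parameter, consistent with the finding that the
spiral lamina is the structure that most influences the potential
reaching the nerve.

## Synthetic data

The generators emulate the three inputs the pipeline consumes. The
canonical 9-landmark outline is a hand-drawn plausible duct
cross-section (normalised to unit basal width, versioned constant, not
traced from any histologic section) whose proportions keep the full
construction valid over two turns; series scale it by decay^(θ/360) with
seeded Gaussian jitter. Measurement tables draw values from the fitted
curves with seeded relative noise; landmark perturbations are isotropic
Gaussian displacements. Everything is a pure function of its arguments
including the seed, and randomness is confined to this module. What the
synthetic data does **not** emulate: real anatomical shape variation
(beyond isotropic jitter), histologic distortion, inter-subject
correlation between parameters, or the modiolar-notch detail of real
medial walls — so passing tests demonstrate the machinery and its
internal consistency, not anatomical accuracy on real sections.

## Known limitations

- The RMSE magnitudes of the published method comparison are not
  reproducible (the underlying histologic coordinates are unpublished);
  only its final-row statistics are, and the basal-turn p-value only to
  ≈ 0.001 from the rounded table.
- The sensitivity analysis is property-based: the published FEM geometry
  (turn spacing, modiolus dimensions, electrode coordinates) is not
  fully specified, so spread magnitudes are model-specific and only the
  dominance ordering is asserted.
- The ligament mid-point caps mean the fitted φ/Hk parameters act on the
  geometry only within the geometrically admissible envelope; sweeps of
  those parameters can legitimately produce zero spread when the cap
  binds across their whole range.
- 2D only: no out-of-plane current spread, no 3D lofting between
  sections, no neural activation modelling; the FEM is purely resistive.
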