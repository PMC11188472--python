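# Modeling and numerical methods

This note documents the models, numerical choices and known limitations of
`ivdfem`. It is the design record of the package; empirical statements below
are all computed by the test suite or the acceptance script.

## Disc geometry and mesh

The disc is idealized as an extruded elliptical cylinder with flat endplates:
height 14 mm (literature average for L4–L5), lateral width 50 mm and
anterior–posterior depth 36 mm by default. Width and depth are
literature-plausible placeholders, configurable in `DiscGeometryParams`; the
height and the 44% nucleus volume share are established average-geometry
values. For an extrusion, a nucleus boundary that is a scaled copy of the
outer ellipse (factor √0.44) gives the requested volume fraction *exactly*,
independent of mesh resolution, because both region boundaries are polygons
sampled at the same angles. The nucleus is shifted 1.5 mm posteriorly by
default (the literature reports a posterior NP position without a printed
offset; the value is configurable).

The annulus is split into 5 radial layers of equal local thickness
(layer 1 = outermost) and 5 equal angular sectors per side from the anterior
to the posterior midline (A…E, mirrored left/right); neither the layer
thickness profile nor the sector angles are published, so the uniform
partition is the neutral choice.

Meshing uses a butterfly (O-grid) topology: a transfinite-interpolated core
block inside the NP, then structured rings to the NP boundary and through
the AF layers, extruded axially. `n_theta` must be a multiple of 8 so the
core-block corners coincide with ring nodes. The default density
(`mesh_density = 1`: 16 angular divisions, 2 axial layers, 256 elements) is
the "coarse default" used for calibration experiments; refinement multiplies
all divisions. Tests additionally use a minimal 8-sector mesh (104 elements)
where only solve cost matters; note that with 8 sectors not every (layer,
subregion) combination contains an element, which is why that mesh is not
the default.

Coordinate convention (fixed package-wide): x = left-lateral, y = posterior,
z = cranial. Load cases: flexion = +x moment, extension = −x, lateral
bending = +y, axial rotation = +z.

## Constitutive models

*Ground substance* (NP always; AF in the rebar models): isochoric
Mooney–Rivlin, `W = C10(Ī₁−3) + C01(Ī₂−3) + (K/2)(J−1)²`. The materials are
treated as nearly incompressible; rather than a mixed/hybrid element
formulation, a volumetric penalty with `K = 1000 × (C10 + C01)` (configurable
`bulk_scale`) enforces `J ≈ 1`. The solver test suite verifies `J ∈
[0.98, 1.02]` in every element at the maximum 7.5 Nm load.

*HGO annulus*: Neo-Hookean matrix plus two exponential fiber families with
dispersion κ ∈ [0, 1/3] and a Macaulay bracket making fibers tension-only.
Isochoric invariants (Ī₁, Ī₄) are used in the fiber strain measure, the
standard convention. The exponent `k₂⟨E⟩²` is clamped at 50 inside the
solver kernels to avoid overflow during line-search trial states; the clamp
is far outside the physical operating range.

*Rebar fibers*: 1-D tension-only laws — linear elastic (`σ = E(λ−1)`,
default E = 220 MPa, a plausible initial-modulus fit for annulus collagen;
the reference value is not published) and a tabulated law integrating a
uniaxial stress–strain curve. The shipped default curve is a synthetic
exponential-toe placeholder (`σ = 1.5(e^{22ε}−1)` up to 25% strain), clearly
labeled as such; the cited experimental curve is not printed anywhere. A
Marlow-type energy construction from the uniaxial curve reduces exactly to
this tabulated 1-D law in the uniaxial rebar setting. The fiber Poisson
ratio ν is stored but inert in a 1-D law; a test asserts this, consistent
with its negligible sensitivity.

*Regional scaling*: the fiber angle (base α, degrees to the transverse
plane) and the fiber stiffness parameters scale per layer step and per
subregion step. Radial and circumferential factors combine
**multiplicatively**, `(1 + r·(L−1))(1 + c·s)`: the one-directional
definitions are stated separately in the literature without a joint rule,
and the multiplicative form keeps each of them exactly true when the other
factor is zero while preserving positivity over the admissible ranges.
Combined angle scalings that push a fiber past 90° are rejected; during
calibration such corners map to a −∞ fitness sentinel instead of an error.

## Finite-element solver

Total-Lagrangian 8-node hexahedra. Selective reduced integration: the
isochoric stress is integrated with the full 2×2×2 Gauss rule, the
volumetric penalty from the element-centroid deformation gradient — the
simplest effective treatment of volumetric locking for near-incompressible
hyperelasticity. 20-node elements are not implemented; requesting quadratic
order raises `NotImplementedError`.

Internal forces are analytic (second Piola–Kirchhoff push-forward); the
element tangent is a forward finite difference of the internal force
(step 10⁻⁶ × mean element size). Newton convergence is judged on the
residual, which is exact, so the difference approximation limits only the
convergence rate, not the converged accuracy. The tangent factorization is
reused across iterations while the residual drops by more than 5× per step
(modified Newton) and reassembled otherwise.

Pure moments are applied through a reference point 10 mm above the top
surface, rigidly coupled to all top-surface nodes with finite-rotation
kinematics (rotation-vector parametrization, Rodrigues map); the bottom
surface is fixed. This mirrors rigid-fixture in vitro loading. The six
reference-point tangent columns are computed by differencing the reduced
residual, which captures the rotational geometric coupling exactly to FD
accuracy. Load increments follow the requested moment grid with automatic
halving (up to 4 levels) on non-convergence; a failed increment flags the
result and returns the partial curve.

Rebar membranes: 4-node quadrilateral patches on the outer boundary surface
of each AF layer, one-point integrated (the coincident solid nodes suppress
hourglass modes). The membrane carries (a) the AF ground-substance
Mooney–Rivlin response in plane stress with exact incompressible thickness
change (λ₃ = 1/(λ₁λ₂)) at thickness 0.1 mm and (b) two rebar families of
equivalent thickness `rebar_area / rebar_spacing` (defaults 0.1 mm² / 0.5 mm
— configurable placeholders; the reference values are unpublished). Membrane
nodal forces are central differences of the patch energy; this keeps the
tension-only kinks of the fiber law consistent between energy and force.

Outcome metrics: RoM is the reference-point rotation projected on the load
axis (degrees, positive in the loading direction). IDP is the
volume-weighted mean hydrostatic pressure `−tr(σ)/3` over NP elements whose
centroids lie within a sampling sphere of radius 25% of the NP half-width
around the NP centroid (the experimental probe location is unpublished;
radius configurable). Moments are N·mm internally, Nm in all I/O.

## OFAT sensitivity analysis

Four equidistant variations per parameter spanning [lower, upper] (bounds
included; the median is covered by the shared reference run), all other
parameters at median; responses are RoM and IDP at 5 Nm for the four load
cases. Scores are signed ratios of percentage changes, averaged per
(parameter, load case, metric); the absolute value enters only the selection
threshold (0.1, boundary inclusive). Bounds are 50%/150% of the literature
median where such a median exists, and the parameter-definition ranges for
the scaling factors. The fiber ν upper bound is capped at 0.499 (150% of the
0.375 median would exceed the physical 0.5 limit); ν is inert in the 1-D
fiber law regardless. Only the HGO and linear rebar models are analyzed —
the nonlinear rebar model differs from the linear one only in its fiber law.

## Genetic-algorithm calibration

Population 20: 6 elites kept unchanged, 4 children by uniform per-parameter
crossover of random distinct elite pairs, 4 mutants (a random elite with one
parameter redrawn uniformly in its bounds), 6 random immigrants. Fitness is
the mean per-load-case R² of simulated vs. reference RoM curves on the
dataset's moment grid (default {1, 2.5, 5, 7.5} Nm); failed solves and
infeasible parameter corners score −∞ and are deselected. Elites are not
re-evaluated (the fitness is deterministic); ties break toward the
earlier-created individual (stable sort). Each model is calibrated in two
steps — stiffness parameters (threshold 0.85, ≤ 20 generations for the
larger steps) then angle parameters (threshold 0.9, ≤ 10 generations) — and
two sequence orders are supported, with NP parameters propagated from the
first model and the nonlinear rebar model inheriting the linear one's
annulus ground substance.

One design choice departs from a purely random initial population: the
incumbent configuration (medians, or the previous step's values) is seeded
as one individual of the initial population. Without it, a step operating on
a parameter subset can end *worse* than the configuration it started from
whenever the generation budget is small, because the incumbent values of the
newly freed parameters are not guaranteed to be sampled; one seeded
individual makes each step monotone in configuration quality and is
statistically irrelevant when budgets are generous.

## Synthetic reference datasets

The in vitro curves used for calibration/validation by comparable studies
(stepwise-reduction RoM to 7.5 Nm on eight specimens, IDP curves, and an
independent RoM dataset to 8 Nm on five specimens) are not publicly
deposited. The `synth` module therefore generates datasets with the same
structure from two sources: the package's own forward model at chosen truth
parameters (exact, zero-noise curves are the reference for recovery
experiments), or a parametric concave-stiffening family
`RoM(M) = a(1 − e^{−M/b}) + cM` with a linear IDP variant, with shape
constants chosen to land in the RoM/IDP ranges reported for disc-only L4–L5
segments. Specimen noise is multiplicative mean-one log-normal (sd 0.1 by
default) — responses are positive scale quantities. The validation-like
flavor is deliberately stiffer in extension than the calibration-like one,
mirroring the qualitative difference between the published datasets.

What passing tests on synthetic data do and do not show: they verify the
pipeline end-to-end (meshing → solving → scoring → optimization →
selection) and the internal consistency of the methods; they cannot certify
agreement with real specimen mechanics, which would require the unpublished
experimental curves, specimen-matched geometry, and a production-scale mesh.

## Problem sizes used by the shipped experiments

The test suite and acceptance experiments run at deliberately small problem
sizes, chosen as the smallest configurations that still exercise every
mechanism: the 256-element default mesh for parameter recovery (GA step 1a,
three seeds), a 104-element mesh with two load cases and a
standard population-20 GA for the order-robustness comparison, and
refinement levels 1, 2 and 2.5 (256 → 3 500 elements) for the
mesh-refinement trend. The calibration
thresholds, the 0.1 sensitivity threshold, and all tolerances are identical
to the full-scale protocol; only mesh resolution, load-case count and GA
budget are scaled.

## Known limitations

* Idealized extruded geometry: no endplate curvature, no patient-specific
  shape; vertebrae, ligaments and facet joints are out of scope.
* Static hyperelasticity only: no viscoelasticity, poroelasticity, osmotic
  swelling, damage, or preload history.
* Trilinear elements with SRI are coarse-mesh-stiff; quantitative RoM values
  converge from below/above with refinement (the mesh study measures this)
  and the coarse defaults are calibration surrogates, not production meshes.
* The OFAT design ignores parameter interactions by construction;
  variance-based sensitivity is out of scope.
* R²-based calibration admits multiple near-optimal configurations; the GA
  history is recorded so alternates can be compared, but only the
  best-fitness configuration is declared calibrated.
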