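# Methods

## Model and assumptions

The ventral collagen layer of a tree-frog digital pad is idealised as a
rectangular, linearly elastic block (length 1.5 mm proximal→distal, width
1.0 mm, height 0.45 mm; ventral face at z = 0) in a consistent mm–N–MPa unit
system. Material is isotropic with E = 20 MPa and ν = 0.33, values within
the range reported for collagenous tissue; the model is small-strain and
quasi-static, with no viscoelasticity, no geometric nonlinearity, and no
fluid (lymph/mucus) mechanics. Three longitudinal rows of five vertical
holes (Ø 0.1 mm) represent the mucus ducts; "hole spacing 0.14 mm" and "row
spacing 0.25 mm" are interpreted as centre-to-centre pitches (edge-to-edge
spacing would spread five holes over more than a millimetre, which is
inconsistent with the rendered geometry, and with a Ø 0.1 mm hole the
centre-to-centre reading leaves plausible 0.04 mm webs). The hole field is
centred in the middle third of the pad length; its longitudinal offset is a
parameter. A quarter-cylinder recess of radius 0.3 × height at the
dorsoproximal edge stands in for the neighbouring phalanx epiphysis — its
true shape is not documented, so shape and radius are configuration
parameters.

The shear load case bonds the ventral face (all displacements zero) and
applies a 3.815 mN tensile load on the solid part of the proximal end face,
directed proximally (−x): the per-digit share of a 7 g body weight
distributed over 18 digits, i.e. the load on one pad of a frog resting
head-up on a vertical substrate.

## Voxel finite elements

The block is voxelised on a regular grid; a voxel is void iff its centre
falls inside a hole cylinder or the recess (no partial volumes — the
geometry tests verify that the voxelised void fraction converges to the
analytic cylinder volume under refinement). Eight-node trilinear hexahedra
with 2×2×2 Gauss quadrature carry the elasticity; element stiffness scales
with density as E(ρ) = E_min + ρᵖ(E₀ − E_min), with a stiffness floor
E_min = 10⁻⁹ E₀ so the constrained system stays definite as voxels empty.
Loads on faces are spread uniformly over solid voxel faces (a quarter of
each face's share per corner node), so nodal sums equal the requested totals
exactly. The reduced system is solved by sparse LU (SuperLU,
`MMD_AT_PLUS_A` ordering in symmetric mode); a Jacobi-preconditioned CG
fallback exists for systems beyond ~2×10⁵ free DOFs. Both honour a relative
residual of 10⁻⁸, checked on every solve, and reactions are verified to
balance applied loads to 10⁻⁶ relative in the tests. Element-centroid
stresses follow from the centroid strain-displacement operator and the
density-scaled Hooke law; principal values are sorted descending (tension
positive) with orthonormal direction triads from a symmetric
eigendecomposition.

## Topology optimisation

The objective is compliance C = fᵀu (minimising it at fixed volume maximises
stiffness) with SIMP penalty p = 3 and the adjoint sensitivity
∂C/∂ρₑ = −p ρₑ^(p−1) (1 − E_min/E₀) uₑᵀk₀uₑ ≤ 0. Sensitivities pass through
a linear-decay smoothing filter (radius 1.5 voxel edges by default) — the
standard mesh-independency device; the reference tool's internal
regularisation is undocumented, so this is the package's own choice.
Densities are updated by the optimality-criteria rule with damping exponent
0.5, bounds [10⁻³, 1] on design voxels, and bisection on the volume-
constraint multiplier to 10⁻⁶ relative, which hits each stage's volume
target to better than 10⁻⁴.

The published stepped schedule is followed: 24 stages, each removing 2.5% of
the initial solid volume, down to 40%. Within a stage the OC iteration runs
until the maximum density change drops below 0.01 (at most 30 iterations).
A plain fixed move limit lets low-sensitivity voxels flip between their
bounds indefinitely, so the move limit is annealed within each stage —
starting at 0.2 and halving every three iterations (floored at half the
convergence tolerance) — which quenches the oscillation and makes every
stage of the pad run converge. Two constraint sets reflect the load case:
holes and recess are hard void (excluded from the design space), and the
ventral voxel layer is frozen at full density, implementing the requirement
that the ventral surface may not be removed.

Geometry, masks and load are mirror-symmetric about the mid-sagittal plane,
so the state equation is solved on a half-width model with the lateral
displacement locked on the mirror plane and half the total load;
sensitivities are mirrored back and the density update is projected onto
exact mirror symmetry. The half model agrees with the full solve to machine
precision (tested) and roughly halves the per-iteration cost. The algorithm
contains no randomness: identical inputs give identical results.

Final shapes are exported by thresholding the density at ρ = 0.5 (marching
cubes → STL); the threshold is a configuration parameter.

## Stress-field analyses

*Trajectories.* Streamlines of the unit maximum-principal-direction field
are integrated with fixed-step RK4 (step = half a voxel edge), interpolating
the six stress components trilinearly between element centroids and
eigen-decomposing at each query point. Eigenvectors carry an arbitrary
sign, so the direction is flipped whenever it reverses against the previous
step; a rotating-axis test field verifies this. Seeds default to a 5×5 grid
just inside the solid part of the proximal face (the recess truncates the
dorsal portion). Integration stops on leaving the bounding box or entering
void/sub-threshold material.

*Webbing contrasts.* Within the longitudinal band spanned by the hole field,
"intra-row" voxels lie within a hole radius of a row centreline (the webs
between consecutive holes of a row) and "inter-row" voxels lie between
adjacent centrelines, farther than a hole radius from both. The report
gives the two von Mises means and their ratio, plus means over four equal
longitudinal quartiles of the whole domain.

*Ridge profile.* The optimised density is averaged over the duct band (full
height) per lateral voxel column; interior local minima/maxima are located
with plateau handling (a flat run lower than both neighbours reports its
centre), since hole rows falling on voxel boundaries produce two-column
plateaus.

## Load budgets and peeling

Tensile capacity is the plain bound area × strength (1 µm² × 1 MPa = 10⁻⁶ N)
with no stress-concentration or fatigue correction. The bundled morphometry
table carries the measured ranges: ventral collagen layer
20,000–65,000 µm² at 100 MPa (collagen), septum 6,500–7,500 µm² at the same
assumed strength (likely an overestimate for its looser weave — no
correction is applied, matching the original estimate), dorsoventral muscle
bundles 7,000–14,000 µm² at 0.2–0.4 MPa (skeletal-muscle strength).
Reference demands default to the 1.27 N single-pad record load and the
3.815 mN per-digit body-weight share (g = 9.81 m s⁻², body mass 7 g).
Budgets report the septum and muscle bundles separately and summed, since
the muscle–septum complex carries the normal load jointly.

The Kendall peel force solves (F/b)²/(2dE) + (F/b)(1 − cos θ) − R = 0 for
its positive root in the rationalised form F/b = 2R / (a + √(a² + 2R/dE)),
a = 1 − cos θ, which is numerically stable in the inextensible limit and
reduces to √(2RdE)·b at θ = 0. R is accepted in J m⁻² (1 J m⁻² = 10⁻³
N mm⁻¹); the default sweep uses R = 50 J m⁻², a mid-range wet-adhesion
energy — the Kendall results used in the analyses are ratios and
monotonicity, which are independent of R.

The septum comparison idealises the septum as a rigid cross-lateral line on
the dorsal face pulled dorsodistally at 70° above the ventral plane (90°
minus the ~20° septum-plane rotation; configurable 60–80°). The attachment
defaults to 0.25 of the pad length: the mucus ducts open distally of the
septum, so its ventral attachment sits just proximal of the duct field,
which begins at 0.28 L in the default geometry. This placement also matters
mechanically — with the ventral face bonded, a pull applied distally of
about 0.3 L localises its tensile peak beneath the attachment line
(St-Venant decay over roughly one block height), whereas proximal
attachments drive the free-edge peeling concentration at the proximal edge.
"Normal contact stress" is operationalised as the z-component of the nodal
reaction on the bonded ventral face divided by the nodal tributary area,
tension (pull-off) positive; its integral balances the applied normal load
component to 10⁻⁶ relative. Because it is unstated whether the original
averaging was signed or tensile-only, both means are reported; the
comparisons use the tensile mean.

## Problem sizes and performance

Pad analyses in the tests, examples and acceptance script run at
30 × 20 × 9 voxels (0.05 mm edge) — the coarsest grid that resolves the
0.1 mm ducts with two voxels across a diameter, and the package's chosen
desk resolution; the volume-reduction bookkeeping the schedule asserts is
resolution-independent. Finer grids (e.g. 60 × 40 × 18, 0.025 mm edge) are
available through the configuration and CLI. The full 24-stage run at the
desk resolution takes a few minutes on one CPU.

## Known limitations

* The reference optimiser (a proprietary Pareto-front tool) is undocumented;
  SIMP + OC reproduces the objective, constraint and schedule, so only the
  qualitative outcome (ridges/troughs, distal flattening, curved
  trajectories) is comparable, not intermediate geometries.
* Trilinear hexahedra are stiff in bending; the cantilever convergence test
  documents ~1% tip-displacement change at the finest doubling. Field
  *patterns* at the desk resolution are robust, absolute compliances carry
  discretisation error.
* The geometry is an idealised box — no curved anatomical surfaces, no
  epidermis, no interphalangeal ligaments; the septum is a line attachment,
  not a fan of fibres. The contact is perfectly bonded: no adhesive
  interface law, so peeling is diagnosed from pull-off tractions rather than
  simulated.
* The morphometry table emulates measured ranges from three frogs; it
  carries no intra-structure variation or measurement error, so budget
  results are bounds, not distributions.
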