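# Methods

`tmjsim` simulates the human temporomandibular joint (TMJ): a
muscle-driven rigid mandible articulating against a static skull
through two fibrocartilaginous disks, with cartilage contact carried by
an elastic-foundation (EF) model.  This note records the model, its
numerical treatment, the synthetic anatomy that stands in for
subject-specific geometry, and the choices made where the design was
genuinely open.

## Model components

**Rigid bodies.**  The mandible is a rigid body with mesh-derived
inertial properties (exact divergence-theorem polyhedral integrals,
uniform density scaled to an assumed mass of 200 g).  Skull and hyoid
are static.  Orientation is a unit quaternion advanced by an
exponential-map increment and renormalized each step.  Gravity
(9.81 m/s² caudally) acts on all dynamic bodies.

**Disks.**  Each TMJ disk is a first-order tetrahedral FEM body with a
two-term Mooney–Rivlin material evaluated on isochoric invariants and
extended by a volumetric penalty,

    W = C1 (Ī1 − 3) + C2 (Ī2 − 3) + κ/2 (J − 1)²,

with defaults C1 = 9·10⁵ Pa, C2 = 9·10² Pa, κ = 1000·C1.  The plain
two-term law has no volumetric response and is ill-posed for a solid;
the penalty enforces near-incompressibility (effective ν ≈ 0.4995).
Disk density is derived from a target disk mass of 6 g divided by the
mesh volume.  Nodal forces come from the analytic Kirchhoff stress;
the tangent stiffness is a central finite-difference linearization of
those analytic forces (vectorized across elements, symmetrized), which
the test suite verifies against independent finite differences.
Elements that invert during violent transients can optionally be
evaluated on an SVD-projected deformation gradient (singular values
clamped at 0.45, reflections removed), which produces a finite,
strongly repulsive response instead of aborting; the synthetic study
model enables this, the `FemBody` default is to abort with element ids.

**Cartilage contact.**  Articular cartilage is an EF layer of thickness
h = 0.4 mm on each rigid articular surface (condyle and fossa, i.e.
both sides of each joint), with pressure

    p(d) = K ln(1 − d/h),   K = −(1 − ν) E / ((1 + ν)(1 − 2ν)),

E = 2.7 MPa, ν = 0.49.  Penetration d is measured inward from the
*outer* cartilage surface, where the law's singularity at d = h
corresponds to full-layer compression; the implementation caps d at
0.99 h with a warning.  Each penetrating vertex contributes a nodal
force f = p(d)·A·n.  For *reported* contact sets the area share A
follows the equal-split rule (total penetrating patch area divided by
the number of penetrating vertices); the *dynamic solver* instead uses
each vertex's constant incident surface area, because the equal-split
value jumps whenever the penetrating count changes and that
discontinuous forcing measurably excites the lightly damped rocking
mode of the jaw.  A sphere-pressed-into-plane oracle validates the
summed force against direct integration of p over the analytic contact
disk.

Occlusal (tooth) contact reuses the same machinery between flat dental
plates with a thicker, much softer layer (h = 1 mm, E = 0.5 MPa) plus
strong normal damping.  This lumps periodontal-ligament and enamel
compliance: physiological tooth intrusion is ~0.1 mm at ~100 N, which
a thin stiff layer cannot reproduce — in early versions a 0.2 mm,
50 MPa layer fired multi-kilonewton impulses at grazing tooth strikes
and drove sustained jaw chatter.  Friction is zero everywhere.

**Muscles.**  Twelve bilateral Hill-type point-to-point lines
(temporalis ×3, masseter ×2, medial pterygoid, lateral pterygoid ×2,
anterior digastric, geniohyoid, mylohyoid ×2).  Tension =
f_max·[a·fl(l̂)·fv(v̂) + fp(l̂)] + c·l̇, clamped non-negative.  Curve
shapes: Gaussian fl with width 0.45; Hill hyperbola fv with a/f₀ = 0.25
and v_max = 10·l_opt/s (mild eccentric plateau at 1.4); exponential
passive toe from l̂ = 1 reaching f_max at l̂ = 1.6.  Parallel damping
defaults to 0.01·f_max·s/l_opt — chosen so the 24-muscle ensemble
leaves the 0.2 kg mandible strongly overdamped (ζ ≈ 9) with ~0.1 s
settling times; an order of magnitude more drag makes the jaw
unphysiologically sluggish.  Optimal fiber lengths default to the
initial path lengths, so the generated posture is an exact passive
equilibrium.  Maximal forces are literature-informed placeholders
scaled so that clench condylar loads fall in the tens-of-newtons range
where a C1 = 0.9 MPa disk operates at sub-MPa stress; literature-scale
closer strengths (~800 N/side) would require the disk to carry several
MPa of contact pressure, which this soft material cannot do without
collapsing to a fraction of its thickness.

**Ligaments.**  Four capsule cables per joint: anterior, medial and
lateral between disk and condyle, posterior between disk and skull.
Slack lengths are the initial path lengths plus +4 / +1.9 / +2.5 /
+7.5 mm respectively; below slack the tension is zero, above it is
k_eff·ΔL with k_eff = modulus·area/slack (modulus 250 MPa over a
nominal 1 mm² cross-section — the modulus-to-spring conversion is a
declared convention).  The anterior ligament wraps a cylinder at the
condyle (tangent segments plus a planar geodesic arc, axial coordinate
interpolated by path fraction).  Disk-side anchors are distributed over
~20 surface nodes with normalized inverse-distance weights, so applied
forces redistribute exactly.

## Time integration

A first-order implicit (Backward Euler) step at dt = 1 ms solves

    (M + dt·D + dt²·K) Δv = dt·(f₀ − dt·K v₀ − D v₀-terms)

where f₀ collects all forces at the start-of-step state and K, D are
the implicit stiffness and velocity-Jacobian.  D includes mandible
drag, FEM Rayleigh damping (β = 2·10⁻³ s), the muscle force–velocity
slope, contact normal damping and a tangential viscous (synovial-shear)
contact damping of 2·10⁻⁴·k_sec per contact — the frictionless contact
model otherwise leaves slow tangential and rocking drift modes of the
mandible-disk-fossa stack entirely undamped, and they grow over a few
hundred milliseconds; the shear term is a viscous regularization, not
Coulomb friction; K includes the (lagged, refreshed
every 8 steps) FEM tangent, muscle length and geometric stiffness,
taut-ligament stiffness and the contact stiffness.  Treating the
muscle terms explicitly is unstable at this timestep: the fv slope
alone is of order f_max/v_max ≈ 10³ N·s/m per active muscle, and the
muscle positional stiffness exceeds the explicit stability bound on
the pitch inertia.

**Contact solve.**  Unilateral contact is regularized: each candidate
contact is a spring from the substrate surface with *secant* stiffness
k_sec = p(d̂)·A/d̂, iterated on the predicted end-of-step depth d̂
(under-relaxed fixed point, at most 5 sweeps), so that at convergence
the constraint force equals p(d₁)·A exactly — a fully implicit
evaluation of the foundation law that never samples the logarithmic
pressure at extrapolated states and cannot eject a contact through the
surface.  Convergence is judged by aggregate force consistency against
the exact law (5%).  Steps whose sweeps do not converge, whose loaded
contacts change depth by more than 0.35 h in one step, or that invert
elements are re-run as two half steps (recursively, two levels).  A
damped-Newton fallback with fresh FEM tangents per iterate engages when
the linearized solve predicts nodal increments above a quarter of the
smallest element edge.  Linear systems are solved by conjugate
gradients preconditioned with a recycled sparse LU factorization
(refreshed when CG stalls); rigid-body dofs are ordered last to limit
factorization fill.  Mandible drag defaults to 50 N·s/m and
0.3 N·m·s/rad — deliberately heavy, quasi-static stabilization of the
joint-bounce modes, still an order of magnitude below the muscle
torques that drive the tasks.

## Synthetic anatomy

Subject-specific geometry is not available, so a parametric stand-in
generates: an ellipsoidal condyle (semi-axes 8×10×7 mm) per side at
±50 mm laterally; a conforming articular fossa whose shape is the
condylar cap plus a degree-3 sagittal / degree-2 mediolateral
polynomial (default a deep glenoid cup, s₂ = 0.08, s₃ = −0.012,
m₂ = 0.05 — zero slope and positive curvature at the seated condyle,
an eminence descent anterior of ~4 mm and a rising posterior wall;
shallow cups let the condyle–disk complex squeeze posteriorly out of
the joint under the up-and-back closer pull); a biconcave disk
(footprint 6.2×7.8 mm, centre 1.2 mm, periphery 2.5 mm, clamped at
1 mm for element quality) meshed between the two cartilage surfaces; a
convex-hull mandible carrying the condylar cartilage and lower dental
plate; flat occlusal plates with a 0.02 mm initial bite clearance; the
muscle and ligament sets above.  The fossa cartilage surface is the
exact offset of the disk top, so the initial state is seated with
clearance everywhere (verified: no initial penetration).

The disk mesh is a prismatic lattice: a hexagonal in-plane point set
with a uniform-arc-length boundary ring, Delaunay triangulated,
extruded through the thickness (≥2 layers) and split into three tets
per prism with an index-ordering rule that keeps shared faces
conforming.  At the default 1.2 mm edge this yields ~1400 tets per
disk with mean circumsphere/shortest-edge ratio ≈ 1.1 and mean maximal
dihedral ≈ 105°.  Randomness (seed) only drives optional left/right
asymmetry and attachment jitter; the default bundle is deterministic
and mirror-symmetric.

**Tasks.**  Four activation schedules: rest (0.08 % closer tone),
maximal opening (lateral pterygoid + submental ramp over 0.25 s,
held), protrusion (maximal lateral pterygoid with low stabilizing
co-activation), clench (closer ramp to 1 over 0.25 s from a light
0.02 occlusal tone, so the jaw clenches from the closed position
rather than falling open during the ramp and re-closing with an
impact).

## Problem sizes and what the desk-scale runs show

The package's standard study conditions are: disk lattice edge 1.2 mm,
dt = 1 ms, rest 1.0 s, opening and clench 0.35 s, and a 15-cell
material grid (C1 ×{0.1, 1, 10}, C2 ×{0.01, 0.1, 1, 10, 100}) run as a
short 50 ms opening window.  These sizes keep the full protocol within
desktop single-core budgets.  Because the synthetic anatomy is a
geometric stand-in and the muscle strengths are placeholders, the
millimetre/kilopascal magnitudes produced here characterize *this*
model only; the meaningful outputs are the verified primitives (the EF
law, the constitutive response, the contact oracle, the integrator
recurrences) and qualitative orderings — clench stresses the disk more
than opening, contact pressures exceed disk maximum-principal stresses
by roughly an order of magnitude, and the final opening position is
insensitive to two orders of magnitude of C2 while extreme C1 cells
may fail.  Stress/pressure comparisons use *end-of-task* map maxima:
running maxima can be polluted by isolated vertices that transiently
hit the 0.99 h pressure cap (e.g. one vertex at the eminence lip at
full opening), which is a numerical guard value, not a field quantity.
One quantitative contract is knowingly unmet at desk scale: the rest
posture retains a viscous creep along the articular surfaces of order
10⁻³ m/s at 1 s, decaying roughly hyperbolically, so a 10⁻⁵ m/s
settling threshold would require tens of seconds of simulated time.  Passing these says the machinery is assembled correctly; it
does not validate against any real subject's anatomy.

## Numerical choices and degenerate inputs

- Hausdorff statistics are symmetric and vertex-sampled (both
  directions pooled; min/max/mean/RMS); the maximum equals the
  classical symmetric Hausdorff distance under vertex sampling.
  Surfaces extracted from tet meshes should be `compact()`ed first so
  interior nodes do not enter the sample.
- Dihedral angles are measured between face planes interior to the
  tet, maximized over the six edges; the circumsphere ratio is bounded
  below by √(3/8), attained by the regular tet.
- Nearest-point queries use a centroid prefilter (k = 16 exact
  refinements) for contact detection and an exhaustive sweep for the
  validation metrics; signs at edge/vertex features come from
  angle-weighted pseudo-normals and are never ambiguous.
- TetGen input accepts 0- and 1-based dialects (auto-detected);
  negatively oriented tets are repaired by a node swap; zero-volume
  tets are an error listing ids.
- Stress maps report per-node volume-weighted averages of the
  element Cauchy tensors; von Mises = √(3/2·dev:dev), maximum
  principal = largest eigenvalue.
- Mesh-resolution comparisons sample nodal von Mises at matched
  material points (barycentric lookup in the coarsest mesh's reference
  configuration) because remeshed disks share no node correspondence.

## Known limitations

- The disk material is purely hyperelastic; no poroelastic or
  viscoelastic behaviour.
- Contact is frictionless; occlusal contact is a flat-plate
  abstraction.
- The mandible drag used for numerical stabilization is larger than
  physiological joint damping, so fast transients are over-damped;
  task end states and orderings are the intended outputs, not
  high-frequency dynamics.
- The synthetic fossa/condyle/disk geometry is a parametric stand-in;
  nothing here reproduces any individual's anatomy, and printed
  magnitudes should not be compared against subject-specific data.
- At dt substantially above 1 ms the contact-FEM coupling can fail to
  factorize during fast phases; dt = 1 ms is the supported operating
  point.
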