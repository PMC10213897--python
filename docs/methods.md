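# Methods

`chewsim` simulates one closing cycle of unilateral chewing with a
kinematic–kinetostatic rigid-body model of the skull–mandible system and
derives the mechanical parameters of the mandibular elevator muscles from
the food's resistance characteristic. This note documents the model, its
assumptions, the numerical choices, and the calibration that produced the
bundled default anatomy.

## Model structure

The mandible is a single rigid body. Both temporomandibular joints are
point-on-plane contacts between a condyle centre and an articular facet:
the non-working (N) condyle slides on a "guide" plane whose orientation
encodes the eminence slope and a medial tilt; the working (W) condyle has
its own, independently oriented fossa facet. Each contact removes one
degree of freedom, leaving the body 4 DOF for the force analysis.

Three elevator muscle groups act per side: masseter (M), medial pterygoid
(MP) and temporalis (T). Muscles are straight lines from a skull-fixed
origin to a mandible-fixed insertion; force acts along the current line.
As the force unknowns, M and MP are merged into a single resultant line V
per side (its anchors are convex combinations of the M and MP attachments),
so the four active unknowns are FT_W, FT_N, FV_W, FV_N — exactly as many as
the model's degrees of freedom.

The external load is the food's resistance force F applied at the occlusal
point IW on the lower first molar of the working side, directed along the
occlusal-plane normal so that it opposes closure. Only the application
point is anatomically fixed; the normal direction is a modelling choice
(the food is compressed flat between the occlusal surfaces).

The coordinate frame sits at the incisal end position IS (intercuspation),
x anterior, y left, z superior, SI metres. The closed pose is the reference
pose.

## Food curves

A specimen of initial height h resists compression with a force that rises
to a peak and then either collapses (brittle: dark chocolate, apple,
carrot) or settles onto a plateau (ductile: chocolate bar, sausage). The
parametric family is

    F(dh) = F_peak * (dh / (p*h))^m                     dh <= p*h
    F(dh) = F_peak * [c + (1-c) * exp(-((dh-p*h)/(w*h))^2)]   dh > p*h

with rise exponent m = 1.1, plateau fraction c (0.02 brittle, 0.55
ductile) and post-peak width w (0.08 brittle, 0.15 ductile). The mild rise
exponent keeps the tangent stiffness of the rising limb within ~10% of the
secant value, matching the near-linear rising limbs of compression tests on
these foods; the ductile plateau keeps the force above half its peak until
at least 90% closure.

Defaults per food: the peak force is recovered by inverting the
force-proportionality relation F_H = R_F · F_max with the working-masseter
row of the bundled reference tables (the maximum occlusal forces themselves
are not tabulated anywhere; the masseter and medial-pterygoid rows give the
same inversion to within 0.2%). The peak position p is the working-masseter
ratio of contraction-at-maximum to total contraction (d 0.50, b 0.47,
a 0.23, c 0.27, s 0.23), which transfers from contraction fraction to
closure fraction because muscle shortening is monotone in closure.

Curves are deterministic. Seeded Gaussian noise is available only for
robustness experiments on exported samples and is off everywhere in the
pipeline.

## Chewing path

The incisal point follows a food-dependent loop in the frontal plane. The
force analysis runs on the closing limb only: chewing begins at BP, the
inferior-lateral extremity of the loop — the incisor deviated toward the
working side and open by the food height h — and the closing stroke sweeps
medially and upward into intercuspation. The stroke is

    y(ζ) = ±w_lat * ζ^q,   z(ζ) = -h * ζ,   ζ: 1 → 0

with q = 1.8, so the lateral deviation decreases monotonically and the
terminal approach into intercuspation is dominantly vertical, as in
recorded chewing cycles. The opening limb (generated only for export
completeness) drops near-vertically and swings out to BP.

The lateral width w_lat is not a free choice: it is solved per food so the
closing arc length equals v_t · t_chew at the constant closing speed
v_t = 0.02 m/s. This resolves the otherwise inconsistent pair of
catalogued heights and chewing times (the arc factor v_t·t/h is ≈ 1.11 for
all five foods) and yields w_lat ≈ 0.42–0.46 h. Time is mapped to arc
length uniformly (|d(y,z)/dt| = v_t to ±0.1%), via a dense cumulative arc
table and monotone (PCHIP) inversion.

One-way lateral return also makes the non-working condylar trajectory a
one-way path (downward, forward and medially during opening), matching the
reference kinematics, and is what allows every elevator muscle to shorten
monotonically during closing; an out-and-back elliptical stroke forces the
non-working temporalis to lengthen during early closing for every plausible
attachment geometry.

## Stage 1 — inverse kinematics

The closing motion is a rotation about the fixed working-condyle centre
(the simulation assumption for unilateral chewing: the working condyle
rotates with negligible translation). Three rotation unknowns are solved
per time step against three constraints: the non-working condyle on its
guide plane and the incisal point on the prescribed frontal-plane path
point (y, z). A Newton iteration on the rotation group (left-increment
parameterisation, analytic 3×3 Jacobian, step damping at 0.3 rad) converges
to |residual| < 1e-10 m in a handful of iterations. Steps are chained
backwards from the closed end pose — where the identity is the exact
solution — so each solve is warm-started by its neighbour and the branch of
the nonlinear system is followed continuously; a guard rejects length
jumps > 1 mm-scale between neighbouring steps.

Outputs: pose history, muscle length series q_j(t) for all lines (M, MP,
T, V, and the three temporalis component lines per side), and the condylar
trajectories with their polyline lengths Δd. Contractions are reported
positive for shortening: Δq = q(0) − q(t) with q(0) the open-mouth (BP)
length.

The default grid is 200 steps; 60–100 steps reproduce peak ratios and path
lengths to better than 0.5% and are used inside calibration loops.

## Stage 2 — kinetostatics

At v_t = 0.02 m/s the mandible's inertia forces are orders of magnitude
below occlusal forces, so each time step is solved as a static equilibrium
(no inertia, no gravity). Two equivalent formulations are implemented:

* production route: the two contact constraints define a 4-dimensional
  space of admissible instantaneous motions (null space of the 2×6 contact
  Jacobian); projecting the four unit muscle wrenches and the food wrench
  onto that basis gives a 4×4 linear system for the muscle magnitudes;
* oracle route: the full 6-equation force/moment balance with the two
  contact normal magnitudes as additional unknowns (6×6).

The two agree to machine precision; the test suite holds them to 0.1%.
Muscle forces must be non-negative and contact reactions compressive;
`validate` mode raises on violation, `exploratory` mode clamps to zero,
warns once, and records the most negative raw value. The equilibrium
residual is checked at < 1e-6 N·m per step.

The V resultant is decomposed back into masseter and medial pterygoid
magnitudes by planar vector decomposition along the two muscles' current
anatomical directions (least squares in the plane they span). This
direction-based split makes the FM/FMP peak ratio food-independent
(≈ 1.115 on the calibrated default), which matches the bundled reference
forces; a PCSA-proportional split (6.80/4.37 ≈ 1.56) would not.

## Stage 3 — temporalis decomposition

The temporalis principal force is distributed post hoc over its anterior,
middle and posterior parts with fixed fractions (0.4794, 0.2907, 0.2299),
the PCSA-proportionality assumption applied with part fractions recovered
from the reference component tables (every food–side case gives the same
three values by per-cell division). The split conserves the scalar sum
exactly; the sagittal direction angles of the principal vector (58°) and
the components (76°, 42°, 22°) are carried as metadata and also orient the
three component attachment lines, which fan out from the coronoid insertion
for the component contraction series.

## Metrics

Per food, muscle and side: maximum force F_H and its time t_H; contraction
at maximum Δq_H and total contraction Δq_C; secant stiffness K = F_H/Δq_H;
intrinsic strength k = F_H/PCSA (components inherit the principal value —
the proportional split leaves force/PCSA unchanged). Across foods:
R_F = F_H/F_max and R_q = Δq_C/h with their coefficients of variation.

Side/muscle asymmetry summaries fix the averaging convention explicitly:
pooled sums for the force deficit, 100·(1 − ΣF_N/ΣF_W), and the
contraction deficit, 100·(1 − ΣΔq_W/ΣΔq_N); per-case means for the
stiffness deficit, the hard/soft texture-group stiffness ratio
(mean K over {chocolate, carrot} vs {bar, apple, sausage}) and the
masseter-vs-medial-pterygoid comparisons. Per-case averaging of the
contraction deficit would give 17.6% instead of the pooled 17.5%; the
pooled convention is the one that reproduces the reference summaries.

The non-linear (tangent) stiffness K(Δq) = dF/d(Δq) comes from a monotone
piecewise-cubic (PCHIP) fit of F vs Δq on the rising limb (≥ 20 samples
required, monotonicity enforced after absorbing roundoff wiggles); the
tangent-at-peak vs secant gap is reported, not suppressed — with rise
exponent 1.1 it is ≈ 10%.

Report tables round the way the reference tables print: forces 0.1 N,
contractions 0.1 mm, K 0.1×10³ N/m, k 0.1×10⁴ N/m², and the comparison
report flags reference cells whose printed K disagrees with their own
F_H/Δq_H by more than 5% (one such cell exists: working-side temporalis
for carrot) instead of charging the discrepancy to the simulation.

## Calibration of the default anatomy

The source skeleton geometry is not distributable, so the landmark set is a
reconstruction: anatomically plausible starting coordinates refined by
bounded least squares until the full pipeline reproduces, per food, the six
case-I force-proportionality coefficients (masseter 1.215/1.042, medial
pterygoid 1.089/0.934, temporalis 0.239/0.204 for W/N) and the non-working
condylar path lengths, with hinge penalties keeping muscle forces
non-negative, joint reactions compressive and the six elevator lines
monotonically shortening, and soft residuals pulling the per-food
contraction ratios dq_C/h toward their across-food mean (the
food-invariance the proportionality analysis relies on). Free parameters (23): condyle position and
intercondylar width, occlusal point IW, the x/z coordinates of the three
muscle origin/insertion pairs, both contact-plane orientations (slope and
medial tilt each), and the V anchor weight. The calibrated set is bundled
as `data/default_anatomy.yaml`; `scripts/calibrate_default.py` regenerates
it and the `calibrate` API exposes the same machinery for custom targets.
Nothing is optimised at run time.

Two deliberate departures from a literal reading of the reference values:

* **Condylar path lengths.** The five reference Δd values are not jointly
  consistent with any geometry in which the path scales with food height
  under the arc-length constraint (Δd/h is 0.33–0.34 for four foods but
  0.375 for sausage). The sausage value carries the calibration weight;
  the other four land within roughly 10%.
* **Contraction proportionality.** In a quasi-static rigid-body model the
  instantaneous work identity Σ_j F_j dq_j = F · d(u_IW·n̂) holds exactly
  along the prescribed motion (the solver satisfies it to machine
  precision, and contact reactions are workless). The reference force
  coefficients and contraction coefficients jointly violate this identity
  by a factor of about two, so no geometry can reproduce both. The default
  anatomy is calibrated to the force coefficients; consequently its
  effective muscle moment arms are small (≈ 1–2 cm — a higher mechanical
  advantage than textbook jaw anatomy) and its simulated Δq_C/h values are
  correspondingly below the reference contraction coefficients, though
  still food-invariant (CV < 2%), which is the property the analysis
  relies on. The fixture-level contraction coefficients are validated by
  direct arithmetic on the bundled tables instead.

## What the synthetic inputs do and do not emulate

The food curves emulate the qualitative shape of compression
characteristics (monotone power-law rise, single peak at a food-specific
closure fraction, brittle drop or ductile plateau) with peak forces and
peak positions consistent with the bundled reference summaries. They do not
emulate specimen-to-specimen variability, strain-rate effects, saliva or
temperature softening, or the progressive comminution of a real bolus; the
model runs a single cycle at constant closing speed with a single rigid
mandible geometry. Passing tests therefore demonstrate internal consistency
of the reconstruction and its agreement with the reference summary
statistics — not predictive validity for a particular subject or food
sample.

## Known limitations

* Muscles are straight force lines without activation dynamics,
  force–length/velocity properties or antagonist co-contraction; stiffness
  here is a load-path property of the solution, not muscle tissue
  stiffness.
* The TMJ is a frictionless point-on-plane contact; no articular disc,
  ligaments or cartilage deformation.
* The working condyle centre is fixed during the cycle (no Bennett shift),
  so the working-side condylar path length is exactly zero.
* Single closing stroke only; the opening phase is generated for export but
  never force-solved.
* The occlusal force direction is a fixed skull-frame normal; food shear
  resistance is ignored.
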