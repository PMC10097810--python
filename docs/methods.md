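# Methods

`spinesim` is a forward-dynamic neuro-musculoskeletal model of the
thoracolumbar spine: a fully articulated chain T1–S1 with six-degree-of-
freedom intervertebral joints, driven purely by muscle stimulation under a
hybrid equilibrium-point controller, with bushing discs, tension-only
nonlinear ligaments and four-element Hill-type muscle–tendon units. This
note documents the model, its assumptions, the numerical choices and what
the desk-scale synthetic geometry does and does not show.

## Rigid-body model

Twenty rigid bodies: the seventeen vertebrae T1–L5, the sacrum S1 (rigidly
welded to the spatially fixed pelvis), the pelvis, and a thin cylindrical
linea-alba body (0.1 g) welded to T12 as the abdominal attachment site.
Ribs enter through their mass only, lumped into the owning vertebra.
Seventeen joints × 6 DOF = 102 free degrees of freedom.

Each vertebra carries one trunk-slice point mass with an anterior/posterior
centroid offset; the set is scaled to 29.4 kg (36 % of the 81.5 kg
50th-percentile male). Two modelling choices matter here:

* **Slice rotary inertia.** A point mass leaves the owning vertebra with
  the tiny rotary inertia of the bone alone, producing kilohertz
  rotational modes that no real trunk has. Each slice's own distributed
  inertia (thin disc, gyration radius 0.12 m) is therefore added to the
  owning vertebra's body inertia, while its mass and centroid offset stay
  a point mass. This is the physically correct statement that the slice
  rotates rigidly with its vertebra.
* **Effective centroid offsets.** The generator's slice offsets are
  *effective* offsets relative to the spinal load line, chosen so the
  upright column is close to sagittal torque balance — mildly
  kyphosis-deepening in the thoracic region and mildly lordosis-deepening
  in the lumbar region, so gravitational settling deepens both curvatures,
  and so that during flexion the forward-swinging trunk mass provides the
  gravitational moment that drives the descent. They absorb trunk support
  mechanisms the model does not contain (intra-abdominal pressure, rib
  cage). The distribution is mildly top-heavy: the upper slices carry a
  shoulder-girdle share.

Because every joint has all six degrees of freedom, relative joint
coordinates and per-body world coordinates are bijective. The equations of
motion are integrated in maximal coordinates (per-body world position of
the composite centre of mass, world rotation vector, linear and angular
velocity): the mass matrix is block-diagonal and no chain Jacobians are
needed. The joint displacements that define the disc bushings — relative
translations and the rotation vector of the relative joint rotation — are
computed from the body poses wherever they are needed.

## Intervertebral discs (bushing elements)

Each joint carries a diagonal 6 × 6 linear bushing: three translational
stiffnesses (anterior shear, lateral shear, compression) and three
rotational stiffnesses (lateral bending, flexion, axial rotation), with
region presets for the thoracic, lumbar and lumbo-sacral levels. The
lumbar lateral-bending value is the raised 200 Nm/rad in all variants.
Damping is a uniform 0.01 (N s/m on force components, N m s/rad on torque
components) — energy dissipation effectively neglected.

The rotational displacement is the rotation vector θ of the relative joint
rotation. Torques computed as −Kθ in rotation-vector space are mapped to
Cartesian joint torques by the transposed inverse left Jacobian of the
exponential map, τ = J_l(θ)^{-T}(−Kθ) with θ̇ = J_l(θ)^{-1}ω — the unique
map that makes the elastic torque the exact negative gradient of
V = ½ θᵀKθ (verified against finite differences and closed-loop work in
the tests). The translational force pair and the torque pair are applied
at a single common material point (the child-side joint point), which
keeps the anisotropic bushing exactly conservative and Newton's third law
exact for full wrenches.

The intradiscal-pressure offset is a constant compressive axial force per
joint, frozen at build time as g times the total body + point mass located
cranially of the joint, applied along the joint's longitudinal axis as an
equal-and-opposite squeeze and reported within the disc's contribution.

## Ligaments

Six ligaments per level (ALL, PLL, LF, SSL, ITV, CAP), each as a bilateral
pair of threads: 12 threads per level over T1/2…L4/5, 192 threads total,
none crossing L5/S1. The static curve of a thread is fixed by two
characteristic points: A (toe-to-linear transition) and B (just before
failure). The implemented curve contract: zero at and below the rest
length l0; a quadratic toe on [l0, lA] with F(l0) = 0, F(lA) = F_A and
slope at A equal to the chord slope (F_B−F_A)/(l_B−l_A); the linear region
through A and B; linear extrapolation past B with a logged warning; the
whole curve clamped tension-only. This is the unique quadratic/linear pair
that passes through both characteristic points with C¹ continuity at A
(C¹ at l0 is given up — for toe-shaped data the slope at l0 is
non-negative and the clamp keeps the curve monotone otherwise). Raw
characteristic forces are divided by three and by the number of parallel
threads. Damping multiplies the elastic force, F = F_el(1 + 3 s/m · dl/dt),
floored at zero.

Rest lengths come from the build pose through the literature prestrains
(ALL 9 %, PLL 13 %, LF 11 %, SSL 9 %, CAP 5 %, ITV none):
l0 = d_build/(1+ε_init), so every thread carries exactly its prestrain in
the neutral position. Capsular threads are built from the facet mid-points
of the caudal vertebra, 8 mm along the facet normal; the facet normal is
near-horizontal so facet sliding during flexion barely strains the
capsule. In the generic geometry the posterior elements (LF, SSL, ITV)
span process to process across the whole segment and the longitudinal
ligaments span the disc plus part of the vertebral walls; with spans of
only a disc height, physiologic intersegmental rotations of 3–4° would
imply >50 % thread strains. The LF and CAP characteristic points (and the
extensible SSL strains) are configuration defaults marked as assumptions,
overridable in the model file.

## Muscle–tendon units

A four-element Hill-type unit: contractile element (CE) and parallel
elastic element (PEE) for the fibre, in series with the elastic tendon
(SEE) and a serial damping element (SDE). The three muscle-specific
parameters derive from anatomy at the build pose, where every muscle is
assumed to sit at its optimal isometric length:

    F_max = σ · PCSA (σ = 23 N/cm²),
    l_CE,opt = m_ratio · l_MTU,   l_SEE,0 = l_MTU − l_CE,opt.

The generic constants (one shared, editable set; all documented
assumptions) are: Hill constants A_rel = 0.25, B_rel = 2.25 s⁻¹; eccentric
saturation 1.5 × isometric with slope ratio 2 at zero velocity; bell-shaped
force–length curve of width 0.45; PEE slack at l_CE,opt, quadratic,
reaching F_max at 1.8 l_CE,opt; SEE with quadratic toe to strain 0.02 and
linear to F_max at strain 0.04; force-dependent SDE (D_SE = 0.3,
R_SE = 0.01). The fibre velocity solves the CE+PEE = SEE+SDE balance in
closed form (quadratic per Hill branch). Activation is a first-order
calcium state γ̇ = m(u−γ), m = 11.3 s⁻¹, mapped to activity through a
sigmoid a = (a_min+(ργ)^ν)/(1+(ργ)^ν) with ν = 2, ρ = 10 and basal
activity 0.005. The sigmoid exponent/scale were chosen so the 2–4 %
co-contraction commands produce physiological standing tone and reflex
gain; a steeper (cubic) sigmoid leaves this desk-scale roster unable to
stand.

Muscle paths are piecewise straight lines between origin, up to two
deflection points and insertion. A deflection point may be constrained to
an elliptic area (via-ellipse); it is then placed at the minimum-
total-length point inside the area (interior allowed, boundary when the
unconstrained shortest path exits), solved by a warm-started scalar
optimisation. The packaged desk roster uses fixed deflection points bound
to intermediate vertebrae; the via-ellipse path is exercised by the unit
tests.

The packaged roster (an editable CSV; 36 bilateral rows, 72 threads)
covers rectus abdominis, external oblique (with digitations to the
mid-thoracic rib levels), internal oblique, psoas major (5 fascicles),
the four erector spinae subgroups, lumbar intertransversarii, lumbar and
segmental thoracic multifidus, and the spinalis group. Two roster choices
proved structurally necessary rather than cosmetic: (i) segmental
two-level multifidus threads in the thoracic region — long, path-
integrated muscles cannot distinguish a single-joint kink from distributed
flexion, so without local reflex loops the thoracolumbar junction buckles;
(ii) abdominal-wall digitations onto the mid-thoracic ribs, the only
anterior muscular restraint that catches transient thoracic extension
during the return (facet and spinous-process contact being out of scope).
PCSAs sit at the literature-upper range.

## Motor control

Stimulation follows the hybrid open/closed-loop law

    u = ½ (u_open + κ (l_CE − λ)/l_CE,opt),  clamped to [0, 1],

with κ = 2.0, equal mixing weights, and open-loop co-contraction levels
0.02 (abdominals) / 0.04 (back), with the lower (0.01/0.03) and higher
(0.03/0.05) variants as pure configuration.

The flexion movement is discretised into target postures in 2° increments
of the lumbar angle change, each mapping every muscle to a desired fibre
length λ. Targets are solved kinematically: the commanded lumbar angle is
distributed over the lumbar joints proportionally to their flexion
compliance, the thoracic joints follow with a configurable share (0.5 per
unit of lumbar angle), all muscles are routed in the resulting posture and
λ is the equilibrated fibre length shifted by the path-length change, so
the upright target reproduces the equilibrated fibre lengths exactly.
Switching is event-based on magnitudes: descent advances at
|Δφ_lum| ≥ a·|Λ|/2 (a = 1.68 generic, 1.76 individualised), the first
commanded target is the −6° entry (start offset), the peak target is held
2 s once |Δφ_lum| ≥ 20°, and the ascent decrements through every 2° step
whenever |Δφ_lum| ≤ b·|Λ|/2 + 0.1 (b = 1.93 / 1.95), initiated with a −6°
offset. The printed switching inequalities mix signs for negative flexion
angles; the magnitude reading is implemented and documented here rather
than asserted as the original intent.

Two additions around the law are this package's own control design:

* **Droop compensation.** A purely proportional law settles short of the
  commanded posture. During descent and hold the *flexor* targets use
  fibre excursions scaled by a gain of 1.3 (a virtual trajectory slightly
  beyond the commanded angle); extensor and segmental-stabiliser targets
  always track the plain commanded posture so the extensor stretch reflex
  brakes the descent at the right angle and local stabilisers never drive
  a joint beyond its commanded angle.
* **Supervisory sampling.** The switching conditions are sampled at a
  finite control interval (0.75 s). Without pacing, the entire target
  ladder cascades within half a second, the trunk falls ballistically and
  the thoracic column — which has no extension stop and only weak local
  protection — buckles irrecoverably.

## Numerics

*Integration.* The muscle force field is continuous but has many mild
derivative kinks (tendon slack points, stimulation clamps, Hill branch
switches, ligament engagement). On the full 72-muscle chain these defeat
the Newton iterations of off-the-shelf implicit steppers: the Jacobian is
refreshed almost every step and steps collapse to sub-millisecond sizes
regardless of tolerance (verified to be independent of Jacobian accuracy).
Protocol runs therefore use a fixed-step split scheme, `method =
"split-rk4"`: classic RK4 on the rigid-body states with the muscle states
frozen within the step (their damped tensions still act), then the calcium
state advanced by its exact exponential and the stiff fibre ODE — whose
relaxation time reaches microseconds at low force — by a safeguarded,
vectorised backward-Euler Newton step. The default step of 5 × 10⁻⁴ s
sits a factor ≈ 2 below the stability limit set by the stiffest
disc/tendon modes. An adaptive implicit path (Radau, with a
connectivity-derived Jacobian sparsity pattern and tolerances exposed in
the configuration, defaults 10⁻⁶/10⁻⁹) remains available and drives the
small-model oracle tests (pendulum period to 0.1 %, step-halving
convergence, energy conservation).

*Settling.* The settling run first relaxes toward equilibrium under
artificial damping — near-critical per-joint dampers capped by the
smallest effective mass plus a world-frame mass-proportional term, tapered
to zero — and then confirms the steady state of the *true* dynamics: all
joint rotation rates below 2 × 10⁻³ rad/s and translation rates below
2 × 10⁻⁴ m/s sustained for 0.5 s (thresholds exposed in the
configuration; the stricter defaults of 10⁻⁴/10⁻⁵ are available for
longer runs). The artificial damping is purely a numerical seeding device;
no reported state is produced under it. The initial state preloads the
disc translations with the static axial compression that balances the
proximal weight plus the intradiscal offset, removing most of the initial
high-frequency transient. The sagittal-balance criterion — the T1 centre
vertically above the L5/S1 joint within a configurable 5 mm — is checked
after settling and reported as a warning when violated (the desk geometry
typically settles 10–25 mm anterior).

*Local FSU stiffness.* k_local is the central difference of the net
sagittal joint torque under a ±0.1° rotation of the single joint (superior
subtree rigid), with the muscles following quasi-statically: fibres
re-equilibrate against the perturbed paths and the calcium state sits at
the tonic stretch-reflex fixed point of the held targets. This measures
the sustained (tonic) stiffness of the posture — the quantity that
co-contraction modulates. Freezing the fibre lengths instead returns raw
tendon stiffness (~3× larger) and hides the activation effect. On a
bushing-only joint the measurement reduces analytically to the configured
rotational stiffness (270 Nm/rad = 4.712 Nm/° for a lumbar joint).

*Load sharing and k_mean.* Per-joint, per-structure wrenches are booked at
output samples as the wrench each structure applies on the caudal side of
the joint cut, in the parent joint frame about the joint centre; their sum
is the net transmitted joint wrench by construction (closure is exact).
Load shares are least-squares linear fits of each structure's contribution
against the joint angle over the descent, evaluated at the joint angle
where Δφ_lum crosses −20° (interpolated), with percentages from the
absolute fitted values. k_mean is the slope of the fitted net torque line
(first/last value pair of the fit, which equals the fitted slope).

## Problem sizes and run times

The shipped study conditions are desk-scale: the full 20-body/102-DOF
chain with 192 ligament threads and a 72-thread muscle roster (the
published model resolves 294 muscle threads; the roster CSV accepts such
an extension unchanged). A settling run covers ≈ 6 s of simulated time, a
complete flexion–hold–return cycle ≈ 14–18 s; at the default step this is
a few minutes of computation each on one core. The test suite runs the
full protocol once and shares it across the analysis checks.

## What the synthetic geometry shows — and what it does not

The parametric generator reproduces the *structure* of the study: counts,
curvature angles (22.5° lumbar lordosis, 22.3° thoracic kyphosis at
build), mass budget, element rosters, prestrain states, and the qualitative
behaviours — settling that deepens both curvatures, a gravity-driven
descent braked by rising back-muscle force, a held peak at −20°, a return
to the equilibrated angle, and local stiffness that increases with
co-contraction in the held posture. Its load-sharing *percentages* and
stiffness *magnitudes* are properties of the synthetic geometry and the
assumed ligament/muscle tables, not reproductions of the published
subject-specific values, which depend on the exact published geometry (the
published open-source model can be ingested through the landmark pipeline
or the model JSON when available; the corresponding benchmarks then
activate in the test suite). At the equilibrated posture the three
co-contraction levels settle ≈ 3.7° apart in this geometry — three times
the published spread — and the posture-dependent ligament engagement then
dominates the small activation effect on k_local, which is why the
monotone activation ordering is evaluated at the held peak, where the
controller pins all levels to the same angle.

Known limitations beyond the source scope (no facet contact, no
intra-abdominal pressure, no extension movements): the desk roster's
muscle moment arms are coarse; thoracic joint excursions during the
movement are larger than physiological because the rib cage is mass only;
and the ascent is faster than the recorded movement because the reduced
roster tracks its targets more loosely.
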