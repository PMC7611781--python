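# Methods

This note documents the models implemented in `cardioloop`, the choices
made where the design was genuinely open, and the limits of what the
synthetic fixtures and tests can show.

## Idealized geometry and fibers

The ventricular fixture is a truncated prolate ellipsoid shell (endocardial
semi-axes 15 mm short / 32 mm long, 10 mm uniform wall, base plane at a
quarter of the long axis above the equator), meshed by a structured
grid in (meridional, azimuthal, transmural) parameters split into
conforming tetrahedra (Kuhn split; apex poles handled by collapsing and
discarding degenerate cells).  The transmural element-layer count is
`max(2, round(thickness / edge))`, so every fixture has at least two
element layers across the wall.  Each cavity is closed by a flat
triangulated lid at the base plane (a fan over the endocardial base ring);
`endo + lid` is verified edge-closed and outward-oriented, which makes the
divergence-theorem cavity volume `V = (1/3) ∮ x·n dΓ` exact and
translation-invariant.

The biventricular variant adds the right ventricle as a second, thinner
truncated-ellipsoid shell beside the left one rather than as a fused
crescent: a conformal fused crescent adds meshing complexity without
changing what the coupled two-cavity solver exercises, and ventricular
interaction through the septum is represented in the 0D TriSeg model.
Consequently the 3D fixture carries no direct mechanical septal coupling —
a stated simplification of the fixture, not of the solver.

Transmural and apicobasal coordinates are harmonic (P1 Laplace solves with
Dirichlet data on the labeled surfaces).  This is a stand-in for richer
universal-coordinate constructions; for these shells it is smooth,
boundary-exact, and all downstream rules need nothing more.  Fibers follow
the rule-based architecture: helix angle linear in the transmural
coordinate from +60° (endo) to −60° (epi) against the local circumferential
direction, sheet direction transmural, right-handed orthonormal triads to
1e-10.  At the apex pole, where the circumferential direction degenerates,
the x-axis projected into the tangent plane is used (deterministic,
logged).

## Electrophysiology

Activation is the first-arrival time field of the anisotropic eikonal
equation with the squared-velocity tensor built from (v_f, v_s, v_n) =
(1.02, 0.68, 0.34) m/s in the fiber frame.  The solver is a vectorized
Jacobi sweep of the classical per-tet local minimization (face, edge and
vertex candidates under the metric V⁻¹), iterated until the largest nodal
update is below 1e-3 ms.  Fast marching is avoided deliberately: 3:1
anisotropy violates its causality assumptions on tetrahedra.  On convex
constant-metric meshes the solver is verified to over-approximate the exact
solution by at most ~2.5% and never undershoot (upwind consistency); an
anisotropic-edge-weight Dijkstra bound is tested on the ventricular
fixture.  Multi-source fields equal the pointwise minimum of single-source
fields up to the mesh-consistency error (tested at half an edge length).
Reaction–diffusion electrophysiology, repolarization and ECGs are out of
scope; the arrival time plus the electromechanical delay (15 ms) clocks the
active stress directly.  Fascicle sites are endocardial balls (6 mm) at
representative antero-septal/septal/posterior positions in universal
coordinates for the LV (septal/moderator-band for the RV); they are
defaults, not subject-specific data, and all fascicles of one ventricle
share the trigger time.

## Solid mechanics

P1 tetrahedra with single-point quadrature (P1–P0).  Passive material:
Fung-type orthotropic energy with volumetric penalty (κ = 650 kPa,
a = 0.7 kPa, b-coefficients 5/6/3/10/2/2); active stress: the
length-dependent tanh² transient (S_peak 100 kPa LV / 80 kPa RV, t_dur
300 ms, τ_c0 = τ_r = 100 ms, ld 5, ld_up 500 ms, λ₀ = 0.7) with 40% of the
force along the sheet direction.  Fiber stretch is read from the current
`C`; velocity dependence is deliberately absent.  The analytic second
Piola–Kirchhoff stress is verified against finite differences of the
energy (relative 1e-5 property test).

Pressure acts as a follower load on the **full closed cavity surface**,
lids included — the lids are the explicitly discretized valve faces — which
makes the discrete pressure load exactly work-conjugate to the enclosed
volume (`dR/dp = −∂V/∂u`), a property the coupling exploits and a test
asserts.  Boundary conditions: omni-directional basal springs
(2 kPa/mm) and reference-normal epicardial Robin springs (0.2 kPa/mm,
optionally scaled by a per-node field; the spatial profile is exposed to
the user and constant by default).

Consistent tangents come from element-level complex-step differentiation
(step 1e-30) of the same residual kernels that build the residual: exact to
machine precision, immune to subtraction cancellation, and verified against
a global FD Jacobian on a two-tet fixture.  Linear solves use a direct
sparse factorization; the contract is residual-based (relative 1e-8 or an
absolute floor of 1e-9 mN for static solves), so an iterative solver could
be substituted.

Dynamics: generalized-α with spectral radius ρ∞ = 0 (α_m = −1, α_f = 0,
β = 1, γ = 3/2) and Rayleigh damping 0.1/ms · M + 0.1 ms · K₀ with the
reference-configuration stiffness.  Time step 1 ms; the initial passive
inflation to the end-diastolic pressure uses 32 equal quasi-static load
increments.  Unloading by backward displacement (fixed point
`X_ref ← X_image − u(inflate(X_ref))`, tolerance 0.1 mm, divergence guard)
is provided and verified by a construct-and-recover test; the generated
fixtures are *defined* as unloaded reference configurations, so the staged
runs do not invoke it.

**Known limitation — volumetric locking.**  At κ = 650 kPa the P1–P0
element locks: on the thick-sphere benchmark the linear-regime displacement
is under-predicted by roughly 2–3× and element pressures checkerboard
across layers.  This is the familiar price of the simple element at
near-incompressibility and coarse resolution; it compresses the fixture
ventricle's filling range and ejection fraction relative to physiologic
hearts.  The Lamé shell verification therefore runs at moderate
bulk-to-shear contrast (κ = 65, a = 7, isotropic b = 5), where the element
is accurate and the Lamé stress field — material-independent for traction
boundary conditions — is matched within a few percent; a separate test
asserts that |J − 1| decreases monotonically with κ.

## Closed-loop circulation (0D)

The 26-ODE state: 4 tube volumes, 4 cavity volumes, contractility `C` and
contractile sarcomere length `L_si` for each of 5 walls (LA, RA, LV free
wall, RV free wall, septum), 6 valve/inlet flows, and the TriSeg septal cap
volume and junction radius.  The derived chain is stateless:
volume → midwall area/curvature → natural fiber strain (with thick-wall
correction z) → sarcomere stress → wall tension → Laplace transmural
pressure → + pericardial pressure → cavity pressure → valve pressure
differences → effective orifice areas.

Sub-laws (each individually testable):

- **Sarcomere**: series-elastic active stress
  `σ_a = σ_act C (L_si − L_si0)(L_s − L_si)/L_se`;
  `dL_si/dt = v_max((L_s − L_si)/L_se − 1)`; contractility rises with a
  smooth pulse `0.02 x³(8−x)² e^{−x}` of the normalized activation clock,
  gated by the length-dependent factor `tanh(4(L_si − L_si0)²)` (the 0D
  Frank–Starling mechanism), and decays after a length-dependent twitch
  duration.  Passive stress is exponential in sarcomere length.
- **Walls**: atria are spherical; the three ventricular walls are spherical
  caps sharing a junction ring (TriSeg).  The septal cap volume and
  junction radius relax toward zero net axial/radial junction tension with
  a 5 ms time constant — fast against the cycle, slow enough not to
  dominate the integrator (measured: 2 ms triples the step count for no
  visible signal change).
- **Valves**: inertial flows `L dq/dt = Δp − Δp_Bernoulli − R q` with a
  smooth (sigmoid in Δp, width 0.05 kPa) effective orifice area between a
  leak area and the open area — no discrete events, keeping the embedded
  error estimate of the integrator valid.  Venous–atrial inlets use the
  same law, always open, with inertance (a modeling choice; plumbed as a
  flag).
- **Tubes**: `p = p_ref (V/V_ref)^k` with k = 1 (linear compliance at the
  reference point) plus a series wave impedance acting on the junction
  flow.  **Pericardium**: a stiff power law on total heart volume adds a
  common pressure to all chambers.

Integration: hand-rolled embedded Fehlberg 4(5) with component-wise scaled
error (atol = rtol = 1e-6), classic safety-factor step control, exact
landing on trigger and synchronization times, and rejection (step ÷ 4) of
stages that leave the admissible region (e.g. a valve-slam overshoot
driving a volume negative).  Total blood volume is conserved to integrator
precision (tested to 1e-6 relative over 20 beats; observed ~1e-15).

**Baseline parameterization.**  The representative canine-scale parameter
set targets the calibration point: heart rate 103 bpm (cycle length
585 ms, atrio-ventricular delay 100 ms, inter-atrial 20 ms, refractory
period 350 ms) and a stroke volume of ~21 mL, i.e. a cardiac output of
~2.1 L/min.  Wall reference areas/volumes and venous pressures were
adjusted once to that working point (measured at the limit cycle: SV
21.5 mL both ventricles, MAP ~90 mmHg, peak LV pressure ~114 mmHg) and
then frozen; they are the package defaults.

## Monolithic 3D–0D coupling

Each PDE cavity contributes `R_p,c = V_c^PDE(u) − V_c^ODE(p_c)` (absolute
mL) and a pressure unknown.  Per 1 ms step, Newton solves the block system
via a Schur complement on the pressures: factorize the mechanics tangent
once per iteration, solve `N_cav + 1` right-hand sides, assemble the dense
`N_cav × N_cav` Schur matrix `G K⁻¹ B + D`, where `D = dV^ODE/dp` comes
from one-sided finite differences (relative 1e-3 with a 1e-3 kPa floor —
small enough to be local, large enough to stand above the adaptive
integrator's noise) on the checkpoint/trial interface of the 0D model.
The 0D model sub-steps adaptively inside each mechanics step, with imposed
PDE-cavity pressures interpolated linearly over the step; trial advances
are pure (checkpoint → trial → commit), so repeated Newton evaluations
cannot corrupt the committed state.

Convergence per step: relative ℓ2 reduction of the mechanics residual
below 1e-6 (with an absolute floor of 1e-6 mN for steps that start at
roundoff, e.g. immediately after static inflation) **and** absolute
`‖R_p‖∞ < 1e-6 mL`.  The semi-implicit mode performs exactly one iteration
per step.  The Schur algebra is verified against a closed-form
linear-surrogate oracle (`p = (V_target − V0)/(C_3D + C_0D)` reached in one
step to machine precision, and against a damped partitioned iteration).

**Staging** (the workflow in `simulate.run_staged`): standalone 0D run to
its limit cycle → re-seat the 0D ventricular volumes on the FE cavity
volumes (the difference is moved to the venous pool, conserving total
volume) → 32-step passive inflation to the 0D end-diastolic pressures →
semi-implicit beats → fully converging Newton beats.  Because the fixture
ventricle is smaller and (through locking) stiffer in filling than the
calibrated 0D chamber, its coupled limit cycle sits at a lower afterload;
the systemic arterial tube is pre-drained to 3 kPa at coupling start to
shortcut that multi-beat transient.  The demonstration beat then shows the
full phase structure — isovolumetric contraction, ejection
(SV ≈ 7 mL on the coarse fixture), relaxation, filling — with every
full-Newton step satisfying the volume constraint to 1e-6 mL in 2–3
iterations.

## Analysis protocols

End-systole is the first downward crossing of the outflow below
1e-6 mL/ms after peak ejection (sub-sample linear interpolation;
no-ejection beats fall back, flagged, to peak pressure).  End-diastole is
the first sample reaching 99.9% of the filling excursion, because the
volume flat-tops while isovolumetric pressure already rises under the
smooth valve law.  ESPVR, pump-function-graph and Starling fits are plain
ordinary least squares; ESPVR fits are independent per contractility level
(no common volume intercept is enforced).  Afterload steps scale R_sys;
the isovolumetric extreme closes the aortic valve (open area → leak area),
and the unloaded extreme uses R_sys × 0.05 (smaller factors push the
linear-compliance arterial tube toward collapse and the integrator into
step-size underflow — a parameterization limit, not a physiologic one).
Preload steps scale the pulmonary venous inlet area; the area must drop
to a few percent of nominal before its Bernoulli resistance limits
filling, so the walk-down schedule spans factors 0.03–0.12.  Contractility
steps scale the active stress of the LV free wall and septum.  Each
protocol records the first post-step beat (initial response) and the beat
after 8 beats (re-stabilized response).

## What the fixtures do and do not show

Everything here runs on idealized, coarse, desk-scale geometry with a
reconstructed 0D parameter set.  Passing tests demonstrate: correctness of
the constitutive laws against their own energies and closed forms;
consistency of the eikonal solver against exact solutions and graph
bounds; exactness of the coupling algebra and per-step satisfaction of the
volume constraint; conservation and sign structure of the closed loop; and
qualitative physiology (E_a ∝ R_sys, ESPVR steepening with contractility,
Frank–Starling monotonicity, decreasing pump function graph).  They do not
demonstrate quantitative agreement with any animal's hemodynamics: the
fixture ventricle's ejection fraction (~25–30% unloaded potential) is
depressed by element locking and the absence of residual strain, and the
0D sub-laws are a faithful-in-structure reconstruction, not a port of any
specific published parameter set.
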