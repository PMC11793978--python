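# Methods

`tailopt` quantifies how much a jointed tail can reorient the body it is
attached to. This note records the model, the optimization machinery,
the synthetic inputs, the numerical choices, and what the desk-scale
experiments do and do not establish.

## Physical model

A torso and a serial tail, both uniformly dense square prisms, connected
by rotational joints. The torso (5 kg, 0.3 × 1.0 × 0.3 m) is pinned to
the ground at its centroid through an **unactuated** 3-DOF rotational
joint, decomposed intrinsic Z-Y-X (yaw, pitch, roll); the configuration
vector stores `(roll, pitch, yaw)` followed by the tail angles. The tail
(1.5 kg, 1.5 m total, 0.1 × 0.1 m cross-section) is divided into `n`
vertebrae; each joint has an actuated pitch DOF (local x) followed by an
actuated yaw DOF (local z) at the same point, placed at the prism end
faces. The tail attaches at the torso's posterior end face. Tail joints
deliberately have no roll DOF: combined pitch/yaw motion manipulates
torso roll, and the reduction keeps the optimization tractable.

Gravity is exactly zero everywhere and no flag re-enables it: inertial
manoeuvring rests on conservation of angular momentum, which holds with
or without a uniform gravity field, so removing it loses no generality
and removes a confound. Because the base pin transmits force but no
torque, the total angular momentum about the attachment point is
conserved even while the tail motors act — the test-suite verifies this
numerically along actuated trajectories.

Mass bookkeeping under varying vertebral lengths: density and
cross-section are fixed, so a vertebra's mass is proportional to its
length (1 kg/m at the reference cross-section) and its centroidal prism
inertia is recomputed from its length. All tails of every design carry
the same total mass and length.

Per-DOF limits (each tail DOF independently): position ±60°, velocity
±360°/s, torque ±5 Nm. Torso states are bounded at ±180° and ±360°/s,
matching the envelope of the target trajectories.

## Target trajectories

Targets are per-axis fifth-degree Fourier series
θ_i(t) = a_i0 + Σ_j a_ij cos(jω_i t) + b_ij sin(jω_i t) over a 0.5 s
horizon, with a_i0 = −Σ_j a_ij so every target starts at zero
orientation. Sampling: a_ij, b_ij ~ U[−1, 1]; ω_i ~ U[2π·0.5, 2π·2]
rad/s (one to two oscillations per horizon); a per-axis target peak
drawn from U[30°, 170°]. Because θ is linear in the coefficients, one
per-axis rescale sets the dense-grid peak exactly, and a second rescale
enforces the ±180° amplitude and ±360°/s rate bounds with a 0.95 safety
margin (rescaling rather than rejection keeps sampling O(1)). In
practice the rate bound binds for most draws, so realized peaks sit well
below the nominal 170°; the bundle still mixes gentle and aggressive
rotations in all three axes. These distribution choices are artifact
defaults (recorded in `tailopt.targets`), not measured quantities.

The 3-DOF base uses Euler angles, so pitch = ±90° is a coordinate
singularity; the amplitude bound plus sampling margin keep targets away
from it, and no solved trial has approached it.

## Tracking problem and transcription

Performance of a design is the minimum integrated squared tracking
error ∫‖Cx(t) − Θ(t)‖² dt achievable by tail torques alone, subject to
state boxes, torque boxes, torque-rate bounds (±200 Nm/s default — the
full torque range in 50 ms; exposed in config), the shared total-effort
cap uᵀu ≤ E, and sphere-based self-collision constraints. E = 50 N²m²
is derived from the single-vertebra tail: one 2-DOF joint at ±5 Nm
gives max uᵀu = 2·25; capping every design at this value equalizes the
actuation budget so differences reflect morphology, not total motor
authority.

Transcription is Hermite–Simpson direct collocation in compressed form:
decision variables are states and controls at the knots of a uniform
grid; the control is piecewise linear (midpoint control = knot average);
midpoint states follow from the Hermite interpolant; each interval
contributes 2nq defect equalities and the objective is the matching
Simpson quadrature. The initial state is pinned at rest at the (zero)
target orientation. The effort cap is enforced at knots and midpoints;
collision constraints at knots.

Collision geometry: the torso prism is covered by three spheres of
radius 0.25 m spaced along its long axis (every prism vertex lies inside
a sphere); the tail carries one 0.07 m sphere per joint connection plus
one at the tip. The sphere at the tail-base joint is rigidly attached to
the torso, so its distance to the torso spheres is constant and those
pairs are omitted from the constraint vector; the remaining pairs give
`3 × n` constraints per knot for an `n`-vertebra tail (the n − 1 mobile
joint spheres plus the tip, against 3 torso spheres). With the ±60°
ranges and the 0.2 m minimum vertebral length,
tail–tail collisions cannot occur and are not modelled.

## Dynamics and derivatives

Mass matrix, Coriolis/centrifugal bias and forward dynamics are computed
by vectorized world-frame recursions (body Jacobians for M; a
zero-acceleration Newton–Euler pass for the bias), batch-broadcast over
whole trajectories. Derivatives are exact: the evaluation path contains
no magnitude or conjugation operations, so complex-step differentiation
(step 1e−100) yields machine-precision Jacobians; control directions use
the closed form M⁻¹S and velocity directions perturb only the bias
recursion. Vertebral lengths flow through the same code path, giving
exact length derivatives for the co-design problem. The test-suite
cross-checks forward dynamics against two independent oracles: a
finite-difference Euler–Lagrange construction using only the mass
matrix, and a fully symbolic Lagrangian derivation (sympy) for the
single-vertebra model.

Forward simulation uses adaptive Runge–Kutta (scipy `solve_ivp`,
rtol 1e−8 / atol 1e−10 defaults). `validate()` re-integrates a solved
trial under its piecewise-linear control interpolant and reports the
maximum state deviation; the default pass threshold is 1e−3 rad at the
desk-scale grid.

## Solving the NLPs

All problems are solved with SciPy. The primary path is the large-scale
interior trust-region method (`trust-constr`) on the full-space NLP with
scaled variables (angles ~1 rad, rates ~2π rad/s, torques ~5 Nm,
lengths ~0.5 m), scaled constraints, exact sparse Jacobians, and BFGS
Lagrangian curvature. Interior-point iterates leave small defect
residuals at finite iteration budgets, so solutions are post-processed
by projected-Newton defect restoration (the defect system is square in
the free knot states), with a bounded least-squares fallback when state
boxes are active. Feasibility is re-checked outside the solver, per
constraint family on its natural scale (effort relative to E, rates
relative to the rate limit), against a 1e−6 tolerance.

Tracking trials use a coarse-to-fine protocol: the labelled multistart
guesses (all-zeros; torso orientation interpolating linearly to the
final target with zero controls; uniform-random states/controls within
bounds) compete on a coarse dt = 0.1 s grid, and the best feasible
coarse solution is interpolated onto the target grid and refined once.
This finds better optima per unit time than a single long fine-grid
solve and removes most cold-start noise.

Two further solver routes exist and are used where they are strong:
a reduced-space method that eliminates the states exactly through the
defect system (a damped-Newton implicit Hermite–Simpson rollout) and
optimizes controls (and lengths) with SQP — robust for small warm
subproblems such as the frozen-controls length step; and a full-space
SQP (SLSQP, dense scaled Jacobians) used as a warm-start refiner.

The warm SQP refiner deserves its own note because SQP iterates are
feasible only in the limit. It is run against *margin-tightened*
bounds (all symmetric boxes, the effort cap and the rate bounds shrunk
by 1–3%), so that a candidate's exact-rollout restoration — whose
state drift the margin absorbs — can satisfy the true constraints.
After the iteration cap, the recent iterate path is walked backward,
each point repaired (effort rescale; Newton defect restoration; exact
implicit rollout of its controls) until one passes the full 1e−6
feasibility re-check; as a last resort the endpoint is blended toward
the feasible warm start until a blend repairs. When nothing repairs —
which happens when the SQP exploited discretization slack and its
trajectory has no dynamically consistent neighbour — the arm falls
back to its interior-point solution, so refinement can never make a
result worse or less feasible.

Profiles: `fast` (dt = 0.02 s, 25 intervals; coarse warm-up dt = 0.1 s;
3 starts) for tests and reproduction runs; `reference` (dt = 0.004 s,
125 intervals, 5 starts, large iteration caps) matching the reference
configuration — hours of CPU per bundle, available but not exercised by
the default test run.

## Co-design of vertebral lengths

The co-design problem adds the lengths L to the decision vector with
Σl_i = 1.5 m fixed and l_i ≥ 0.2 m (the bound that keeps the sphere
collision model valid without tail–tail constraints). Dynamics,
collision geometry, mass and inertia are functions of L with exact
complex-step derivatives.

Cold joint solves of this problem at desk scale are unreliable, so
`solve_codesign` proceeds from the solved uniform problem, whose
solution is feasible for the co-design problem (feasible-superset
property — the returned cost therefore never exceeds the uniform cost):

1. **discovery** — warm full-space SQP over (states, controls, lengths)
   from the uniform optimum;
2. **repair** — small effort-cap overages are removed by a global
   torque rescale, defects are Newton/least-squares restored, and a
   shrink-to-fit rollout (slightly scaled-down controls integrated
   through the exact implicit rollout) produces a strictly feasible
   trajectory when the restored point still grazes its boxes;
3. **length polish** — a small SQP over the lengths alone with controls
   frozen, states following through the implicit rollout.

Because the discovery step also refines the controls, the uniform arm
of every paired comparison receives the same warm SQP budget
(`experiment.sqp_polish`); the reported uniform-vs-co-designed
difference therefore isolates the morphology rather than unequal
optimization effort.

## Statistics

Cross-configuration comparisons use one-way ANOVA with Tukey HSD
post-hoc pairs (scipy) and the symbol scheme ***, **, *, ., () for
p < 0.001, 0.01, 0.05, 0.1, ≥ 0.1; uniform-vs-variable comparisons use
classical paired t-tests on per-trajectory differences; α = 0.05
throughout, with no correction beyond Tukey. Improvement percentages
are reported as 100·(1 − mean_new/mean_ref) (ratio of bundle means);
the mean of per-trial ratios is computed alongside since the two
summaries differ under heterogeneous trials.

## Morphometrics

Vertebral series (per-specimen proximal-to-distal centrum lengths) are
normalized by the first caudal vertebra — removing body-size scale, as
first-vertebra length tracks body size — and the crescendo–decrescendo
steepness is summarized by the maximum absolute difference between
neighbouring normalized lengths (a signed variant is exposed; the
absolute form is the default since the crescendo slope dominates real
tails either way). Groups (inertial-manoeuvring specialists vs
non-specialists) are compared with Welch's unequal-variance t-test
(fractional degrees of freedom). The synthetic table generator produces
smooth noisy crescendo–decrescendo profiles with group-level maximum
neighbour differences calibrated to 0.9 (specialists) and 0.3
(non-specialists) and vertebral counts near 28.6 and 25 — it emulates
the *shape and contrast* of comparative skeletal data, not phylogenetic
structure, measurement error covariance or allometry, so passing tests
demonstrate the statistics pipeline, not a biological result.

## Desk-scale experiments: sizes and what they show

The reference experiment (100 trajectories, dt = 0.004 s, five starts
per program) is hours of CPU; the bundled reproduction runs use the
`fast` profile and small seeded bundles — 2 trajectories for the
uniform-tail comparison (n = 1 vs 6, with the six-vertebra arm given
wider multistart and refinement budgets so both arms reach comparable
optimality) and 1 trajectory for the paired co-design comparison
(n = 2, 3, 4) in `scripts/acceptance.py`; the test-suite uses
2-trajectory bundles for both. These sizes are the package's choice of
desk scale, set by the cost of the SciPy solver stack on one CPU.

What the desk-scale numbers show — and do not. The direction of both
effects is robust at these sizes: per-trajectory tracking error falls
as vertebrae are added, and co-designed lengths never track worse than
uniform ones (by construction of the pipeline) and usually track
better. The *percentages*, however, carry two systematic pressures
beyond small-bundle noise. First, per-trial improvements are strongly
trajectory-dependent (roughly 10–55% for six-vs-one vertebra; 1–20%
for co-design), so a handful of trajectories can sit well off the
bundle mean of a 100-trajectory experiment. Second, iteration-capped
local solves leave both arms of every comparison somewhat above their
true minima, and shared inflation shrinks relative differences toward
zero — both headline percentages are therefore conservative
(biased low) relative to fully converged solves. Anyone wanting
publication-scale numbers should run the `reference` profile with a
100-trajectory bundle.

## Known limitations

* The NLP solves are local and iteration-capped; reported errors are
  upper bounds on the true minima. The coarse-to-fine multistart
  mitigates but does not eliminate local-minimum scatter.
* The torque-rate bound (±200 Nm/s) is a modelling choice with no
  measured counterpart; sensitivity to it is exposed in the parameters.
* The collision model is spheres at joints and tip only; deep-fold
  configurations excluded by the ±60° ranges are not otherwise guarded.
* Euler-angle torso coordinates have a pitch singularity at ±90°;
  targets are sampled away from it but the dynamics make no attempt to
  reparameterize near it.
* The tail joints are ideal independent torque sources; real caudal
  musculature couples joints through long tendons, which would reduce
  achievable performance.
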