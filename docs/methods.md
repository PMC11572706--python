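# Methods

`colvarkit` implements collective-variable (CV) components and biasing
algorithms for enhanced-sampling molecular simulation, together with a
minimal Langevin "toy" engine on analytic potentials.  The engine exists so
that every CV and bias can be exercised and verified end to end against
closed-form references, without an external MD code.  This note records the
models, the numerical choices, and what the verification studies do and do
not demonstrate.

## Toy engine

Point particles move on analytic potentials (harmonic well, 1D quartic
double well `U = h(x² − 1)²`, a corrugated 2D surface, a flat landscape
with half-harmonic walls, and a λ-coupled pair of harmonic wells) under
Langevin dynamics integrated with the BAOA splitting: a full-step kick (B),
a half-step drift (A), an exact Ornstein–Uhlenbeck velocity update (O), and
a second half drift (A).  Units are Å, fs, amu, kcal/mol and K, with
k_B = 0.0019872041 kcal/(mol·K) (overridable) and the acceleration
conversion 1 kcal/mol/Å/amu = 4.184·10⁻⁴ Å/fs² from 1 kcal = 4184 J.
Friction is given in 1/ps.  With friction and temperature at zero the
scheme reduces to the symplectic kick–drift map, so the total energy —
evaluated with the on-step (midpoint) velocity, since the splitting stores
velocities half a step off the positions — shows no secular drift.

Randomness comes from one PCG64 generator per walker whose full state is
serialized into checkpoints, which is what makes a restarted run continue
bitwise-identically: the checkpoint holds positions, velocities, the
generator state, and every bias's internal state as canonical JSON whose
floats print with shortest round-trip precision (write → read → write is
byte-identical).

Extended (fictitious) variables — the eABF spring partner and the
alchemical λ — integrate with the same BAOA step.  Their masses are
expressed in kcal/mol·fs²/(CV unit)² so acceleration is force/mass with no
conversion.  Defaults are derived from two physical targets: the coupling
from a target thermal fluctuation σ (k = k_BT/σ²) and the mass from a
target oscillation period τ (m = k(τ/2π)²).  Reflecting bounds mirror the
position across the violated edge and negate the velocity, so λ never
leaves [0, 1] (asserted every step in the tests).  These defaults are
choices of this package; nothing in the underlying method fixes them.

## Collective variables

Geometric components (distance, axis projections, angle, polar angles,
best-fit RMSD, Euler angles) return a value plus dense per-atom gradients.
The best-fit rotation is the top eigenvector of the 4×4 Kearsley overlap
matrix; its derivative with respect to the input coordinates follows from
first-order eigenvector perturbation theory,
dq = Σ_m (v_mᵀ dS q)/(λ_top − λ_m) v_m, which is validated against finite
differences rather than any transcribed formula.  A fit whose top
eigenvalue gap falls below 10⁻⁸ (collinear or coincident points) is flagged
degenerate and refuses to differentiate.  The quaternion sign is fixed by
q₀ ≥ 0, ties broken by the first nonzero component.

Euler angles use the intrinsic z-y-x (yaw–pitch–roll) convention with the
standard quaternion projections; the arcsin argument of the pitch is
clamped and near-gimbal inputs warn.  Angles are reported in degrees,
period 360°, range (−180°, 180°]; the azimuth on the polar axis is defined
as 0°.  The convention is pinned by round-trip tests (angles → quaternion →
angles to 10⁻⁹ degrees away from gimbal lock) rather than by reference to
any external convention table.

A moving frame of reference centers coordinates on a fitting group,
rotates them onto the fitting reference with the best-fit rotation, and
evaluates any inner component on the fitted coordinates.  Biasing forces
propagate to the fitting atoms through the derivative of the rotation and
the centering; the special case of an RMSD whose atom group equals the
fitting group has identically zero fitting gradients and is
short-circuited.  The full chain (CV atoms plus fitting atoms, including
overlapping groups) is finite-difference checked at 10⁻⁵ relative error.

Path CVs come in the softmax (arithmetic) form — progress
s = Σᵢ (i/(N−1)) e^(−λDᵢ) / Σᵢ e^(−λDᵢ) and tube
ζ = −(1/λ) ln Σᵢ e^(−λDᵢ), with Dᵢ the c-weighted squared distance to node
i and all exponential sums max-shifted for stability — and the geometric
form, which projects the current point on the local segment geometry
around the nearest node (vectors to the nearest, second- and
third-nearest images) and yields unique s and ζ values.  Normalization is
pinned to s(node 0) = 0, s(node N−1) = 1.  λ defaults to the inverse mean
squared inter-node displacement.  Nearest-node ties break toward the lower
index; at chain ends the missing third neighbor is linearly extrapolated.
The arbiter for the geometric form is a dense-polyline projection oracle:
on straight and gently curved paths the computed (s, ζ) match exact
projection.  Cartesian-space variants superpose the configuration (and the
node frames themselves) onto a common reference frame via the rotation
machinery and then reduce to the CV-space forms on the flattened aligned
coordinates.

Dense feed-forward neural-network CVs (`x_k = f_k(W_k x_{k−1} + b_k)`,
activations linear/tanh/sigmoid/relu, relu subgradient at 0 fixed to 0)
read plain-text weight files — a `layers` line, an `activations` line,
then row-major matrices and bias vectors — and return exact chain-rule
Jacobians.  The file layout is this package's own; compatibility with any
other code's weight files is not claimed.

Custom scalar functions of other CVs parse a small expression grammar
(`+ − * / ^`, parentheses, sin/cos/tan/asin/acos/atan/atan2/exp/log/sqrt/
abs) into an AST evaluated with forward-mode automatic differentiation, so
partials are exact; parse errors carry the character position and domain
errors the offending value.  Weighted sums of powers (Σ cᵢ ζᵢ^pᵢ) are a
separate, simpler combination component.

Volumetric-map CVs sum a trilinearly interpolated scalar field over a
group's atoms; atoms outside the grid contribute zero value and zero
gradient (the natural choice for occupancy-style maps; the alternative of
clamping would make the CV discontinuous).  Linear interpolation
reproduces linear fields exactly and converges quadratically on smooth
ones.

The DEER (double electron–electron resonance) forward model predicts the
time-domain signal of a spin pair at distance r (nm):
F(t) = [(1−Λ₁) + Λ₁ k(t, r)] exp[−(Λ₂|t|)^(D/3)], with the dipolar kernel
k(t, r) = √(π/6ωt) [C(z) cos ωt + S(z) sin ωt], z = √(6ωt/π),
ω = K_dip/r³, C and S the Fresnel integrals (SciPy's convention), and
K_dip ≈ 327 rad·µs⁻¹·nm³ computed from g = 2.0023, μ_B, μ₀ and ℏ.  Below
ωt = 10⁻⁴ a series expansion of the powder average
∫₀¹ cos[(3u²−1)ωt] du ≈ 1 − (2/5)(ωt)² removes the 1/√t singularity so
k(0, r) = 1 exactly; the closed form agrees with numeric quadrature of the
powder average to better than 10⁻⁶ over ωt ∈ [0, 100].  Ensemble traces
average the kernel inside the bracket.  Background parameters (Λ₁, Λ₂) are
fitted by bounded least squares (Λ₁ ∈ [0, 1], Λ₂ ≥ 0) with tight
convergence tolerances; non-convergence raises with diagnostics.

## Biases

**Harmonic restraints** use wrap-aware displacements for periodic CVs.

**ABF.**  Classic ABF accumulates the instantaneous free-energy-gradient
estimator per bin and applies minus the running mean, ramped linearly
until `full_samples` (default 200) samples.  On the toy systems the
estimator is implemented only for CVs linear in the Cartesian coordinates
(the bare physical force projected on the constant CV gradient), which
avoids the full inverse-gradient formalism; everything else goes through
the extended-system route.  Per-bin sums are held as exact Shewchuk
partial expansions, so pooling walker data is associative: the pooled
state is bitwise identical to a single walker fed the concatenation of all
samples, in any pooling order.  The multiple-walker error estimate is the
count-weighted standard deviation of per-walker bin means (weighting by
sample count, the simplest consistent choice); the integrated free-energy
error assumes independent bins.  Dispersions below 64 machine epsilons of
the pooled mean are reported as zero, since rounded per-walker means of
identical data can differ by one ulp.

**eABF + CZAR.**  Each CV is tethered to a fictitious particle by a spring
(equal and opposite forces, verified); ABF acts on the fictitious
coordinate.  CZAR recovers the unbiased gradient:
A′(z) = −(1/β) d ln ρ̃(z)/dz + k(⟨λ⟩_z − ⟨z⟩_z), with the log-density
derivative by centered differences (one-sided at the edges) and — one
refinement that matters — the spring term built from the conditional
*in-bin means of both λ and z*.  Using the bin center instead of ⟨z⟩_bin
leaves a discretization bias proportional to k·w² that the stiff spring
amplifies well past the few-percent level.  Bins under a minimum count
(default 10) are masked, never interpolated.  In the verification study
the CZAR accumulators restart after a burn-in (1/6 of the run) because the
estimator assumes a stationary bias, and the fitted slope excludes the two
outermost bins on each side (one-sided stencils) and weights bins by their
counts.

**λ-ABF.**  The alchemical λ is an extended variable reflected into
[0, 1]; the gradient estimator is ∂U/∂λ of the coupled potential.  The
λ-coupled toy is a linear interpolation of two harmonic wells, chosen so
the free-energy difference has the closed form
A(1) − A(0) = (k_BT/2) ln(k_b/k_a).

**Metadynamics.**  Hills are projected onto a grid at deposition (values
and analytic gradients at bin centers, truncated at 6σ — a projection
necessity independent of the reflection cutoff) and multilinearly
interpolated; an exact hill-sum evaluation remains as the debug reference
for the projection.  Widths come either per dimension in CV units
(`gaussianSigmas`) or as a single number of grid points (`hillWidth`),
mutually exclusive.  Well-tempered scaling multiplies the height by
exp(−V/(k_B ΔT)).  The boundary correction mirrors every hill deposited
within `reflectionRange` (default 6) σ of a domain edge across that edge —
including all multi-edge combinations, so a corner hill gains 3 images in
2D — with unchanged height and width; outside a non-mathematical boundary
the force component along the exceeded dimension is zeroed and the
potential frozen at its boundary value, avoiding discontinuities at the
walls.  Reflected images are ordinary hills at evaluation time; the
outside-boundary force rule is applied irrespective of how the bias under
it was built.

**EBMetaD** scales hill heights by 1/(e^{S_ρ} ρ_exp(ξ)), with the target
density held on a grid and its differential entropy S_ρ = −∫ρ ln ρ by grid
quadrature; a uniform target reduces exactly to standard metadynamics, and
depositing where ρ_exp = 0 is rejected with a diagnostic.  At convergence
the free energy is recovered as A = −(V + (1/β) ln ρ_exp) up to a
constant.  Because heights scale with the *inverse* target density, a
target whose density spans many orders of magnitude produces enormous
hills in its tails; practical targets (like the verification study's
60/40 Gaussian mixture with σ = 0.5, min/max ratio ≈ 0.22) keep that
ratio moderate.

**Bias exchange** applies the Metropolis rule
min{1, exp(−β[(V_a(x_b) + V_b(x_a)) − (V_a(x_a) + V_b(x_b))])}; on
acceptance the bias-to-replica permutation swaps and persists through
checkpoints.  All CVs are always recorded regardless of which bias is
active.

**Maximum-entropy restraints.**  ALB applies V = λξ and updates
λ ← λ + c(t)(⟨ξ⟩ − ξ_tar) every update period, with ξ_tar pinned to the
experimental value; the running mean is exponentially weighted
(configurable time constant), which keeps the update Markovian and
checkpointable.  For a Gaussian observable the converged coupling has the
closed form (μ₀ − ξ_tar)/(βσ²), the study's reference.  RAD evolves the
target as well: it drifts in the direction that lets the bias relax
(+λη), is pulled back toward the experimental value by γ(ξ_tar − ξ_exp)/η,
and γ adjusts multiplicatively to hold |ξ_tar − ξ_exp|/η at the configured
agreement level (default 1).  Target moves are bounded by η/2 per update
so the η → 0 limit pins the target to the data (the ALB limit) without
overflow.  This concrete update scheme is this package's own construction;
its contract is the three tested limits — η → 0 reduces to ALB, an
incompatible target settles at the agreement level, and a compatible
target lets the coupling decay to zero.  Only observables linear in their
model parameters are supported.

**Histogram restraint** applies harmonic penalties on the across-replica
mean of kernel functions (Gaussian or rectangular) on a 1D CV; replicas
outside every kernel contribute zero.  Plain replica averaging is used —
no mean-field N² rescaling, which belongs to the spin-label multiple-copy
variant rather than the general method.

**ABMD** (ratchet-and-pawl) keeps a high-water mark ξ_ref, monotone in the
chosen direction and capped at ξ_stop, and applies a one-sided harmonic
½k(ξ − ξ_ref)² only when the coordinate retreats; ξ exactly at the mark
feels no force.

**Poisson integration** of 2D/3D gradient grids solves the least-squares
problem min‖∇_h A − G‖² on staggered (midpoint-averaged) differences; the
normal equations are the discrete Neumann Poisson problem, solved by
conjugate gradients (relative tolerance 10⁻¹⁰) with the constant nullspace
projected out and the gauge fixed by min A = 0.  The staggered scheme is
exact for affine gradient fields, so a quadratic surface is recovered to
solver tolerance; rotational (curl-carrying) input is dropped by the
projection and reported through the least-squares residual.

## Configuration, formats, CLI

Configurations are brace-delimited keyword blocks with the field's usual
keyword names (`fittingGroup`-style camelCase, `gaussianSigmas`,
`useHillsReflection`, `replicaID`, ...).  Atom numbers are 1-based in
files, 0-based internally.  Unknown keywords fail with their line number;
`hillWidth`/`gaussianSigmas` exclusivity and dangling CV references are
checked at parse/build time.  Trajectories use XYZ (positions) and a
`.colvars.traj`-style table (header naming columns, `%.14e` values, vector
CVs expanded to indexed columns; NaN refused at write time).  Grids
(gradients, FES, target densities) share one text format; volumetric maps
and NN weights have their own documented text layouts.  The CLI
(`colvarkit run | analyze | integrate | fixtures | deer`) is a thin layer
over the library; `analyze` recomputes CV columns from a stored XYZ
trajectory and reproduces the run-time columns to 10⁻¹⁰.

## Verification studies and their scope

The reference experiments (in `colvarkit.experiments`, shared by the test
suite and `scripts/acceptance.py`) run at 300 K with run lengths of
2.5–6·10⁵ steps chosen so each study finishes in minutes on one CPU while
keeping its statistical uncertainty several times smaller than the margin
it must meet:

* well-tempered metadynamics (bias factor 10, hills 0.08 kcal/mol, σ 0.1,
  every 500 steps) reproduces the h = 2 kcal/mol double well to
  RMSE < 0.3 kcal/mol;
* the boundary correction on a 6 Å walled flat landscape (hills of
  0.006 kcal/mol and σ 0.2 Å every 100 steps, 10⁶ steps with the first 3/8
  as burn-in) cuts the boundary-region error — the RMS of −k_BT ln ρ over
  bins within 1 Å of a wall, referenced to the domain center — to
  < 0.2 kcal/mol (in practice the no-bias statistical floor) and to less
  than half the uncorrected error under identical sampling;
* EBMetaD matches its Gaussian-mixture target (Kolmogorov–Smirnov
  statistic < 0.05) and recovers the double well from V + (1/β) ln ρ_exp;
* eABF + CZAR recovers the harmonic mean-force slope within 5% (across
  seeds the observed scatter is ~2–3%);
* four-walker λ-ABF recovers (k_BT/2) ln(k_b/k_a) within three
  dispersion-based standard errors;
* ALB converges to its Gaussian closed form within 5%; RAD satisfies its
  three limits; ABMD shortens the median barrier first-passage time over
  20 paired seeds.

These studies demonstrate correctness of the algorithms against analytic
references on low-dimensional toys with a single particle and perfect
(analytic) forces.  They do not probe force-field realism, solvent
effects, high-dimensional CV spaces, sampling efficiency at realistic
system sizes, or engine-integration concerns — the toy engine samples the
exact model distribution, so agreement here verifies estimator and bias
implementations, not their behavior on hard molecular landscapes.

## Known limitations

* Classic ABF's projected-force estimator is restricted to CVs linear in
  Cartesian coordinates; nonlinear CVs must use eABF.
* CZAR is implemented for 1D grids (the estimator's common use here);
  multi-D eABF accumulates but does not yet estimate.
* The geometric path form assumes reasonably smooth, non-self-intersecting
  node chains; the tube gradient is singular exactly on the path.
* Bias-exchange is provided as primitives (acceptance test + permutation
  bookkeeping), not a full synchronous replica scheduler.
* No pairwise force fields, minimum-image machinery, or thermostats other
  than Langevin; one- and two-dimensional bias grids only.
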