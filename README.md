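# colvarkit

Collective-variable components and biasing algorithms for enhanced-sampling
molecular simulation, with a built-in Langevin toy engine so every method
can be exercised and verified end to end on analytic model systems — no
external MD engine required.

## Who this is for

Method developers and students of enhanced sampling who want reference
implementations of collective variables (CVs) and adaptive biases whose
every gradient, estimator and bookkeeping rule is checked against an
independent oracle: finite differences, closed forms, numeric quadrature,
or brute-force enumeration.

## What is implemented

**Collective variables** ξ(X), each with analytic per-atom gradients:

* geometric components — distances and axis projections, angles, polar
  angles (θ, ϕ), best-fit RMSD, and Euler angles (roll Φ, pitch Θ, yaw Ψ)
  from the quaternion of the optimal superposition;
* moving frames of reference: any CV evaluated in the frame of a fitting
  group, with biasing forces propagated to the fitting atoms through the
  derivative of the best-fit rotation (4×4 overlap eigenproblem
  perturbation theory);
* path CVs: progress s and tube ζ in the softmax (arithmetic) and
  geometric (unique-valued) formulations, in CV space and, via
  superposition, in Cartesian space;
* dense neural-network CVs with plain-text weights and exact Jacobians;
* DEER spectroscopy forward model: dipolar kernel
  k(t, r) = √(π/6ωt)[C(z) cos ωt + S(z) sin ωt] with ω = K_dip/r³, full
  background-damped signal, trajectory averaging and background fitting;
* custom closed-form expressions of other CVs with forward-mode automatic
  differentiation, weighted sums of powers, and volumetric-map CVs
  (trilinear interpolation).

**Biases**:

* ABF, extended-system ABF with the CZAR estimator
  A′(z) = −(1/β) d ln ρ̃/dz + k(⟨λ⟩_z − z), multiple-walker ("shared") ABF
  with bitwise-exact pooling and a dispersion-based error estimate, and
  λ-ABF on an alchemical coupling parameter reflected into [0, 1];
* Poisson integration of 2D/3D gradient grids into free-energy surfaces;
* grid-projected metadynamics with well-tempered scaling, a
  reflection-based boundary correction (mirror-image hills near domain
  edges, zeroed outward force components beyond walls), ensemble-biased
  metadynamics (EBMetaD) targeting an experimental distribution, multiple
  walkers and bias-exchange moves;
* harmonic restraints, maximum-entropy average restraints (ALB and RAD),
  the multiple-replica histogram restraint, and adiabatic-bias MD
  (ratchet-and-pawl).

**Engine and plumbing**: BAOA Langevin integration on analytic potentials,
extended variables with reflecting bounds, serializable per-walker RNG
(bitwise-reproducible restarts), a Colvars-style keyword-block
configuration dialect, XYZ / `.colvars.traj` / text-grid formats, and a
CLI (`run`, `analyze`, `integrate`, `fixtures`, `deer`).

## Worked example

Free-energy recovery by well-tempered metadynamics on the 1D double well
U = h(x² − 1)², h = 2 kcal/mol, at 300 K:

```python
import numpy as np
from colvarkit.engine import EngineParams, Simulation, SystemState
from colvarkit.potentials import PotentialSpec
from colvarkit.geometry import AtomGroup, DistanceZ
from colvarkit.grids import Grid
from colvarkit.metad import MetadState, MetadBias

pot = PotentialSpec("double_well_1d", {"h": 2.0})
params = EngineParams(temperature=300.0, friction=20.0, timestep=1.0, seed=1)
state = SystemState([[-1.0, 0.0, 0.0]], [[0.0, 0.0, 0.0]], [1.0])
x = DistanceZ(AtomGroup([0]), axis=(1, 0, 0))

grid = Grid.make([-1.7], [1.7], [68])
bias = MetadState(grid, sigmas=[0.1], height=0.08,
                  well_tempered_delta_t=2700.0)        # bias factor 10
metad = MetadBias([0], bias, period=500)

sim = Simulation(pot, params, state, colvars=[x], biases=[metad])
sim.run(500_000)

centers = grid.centers(0)
fes = -(300.0 + 2700.0) / 2700.0 * bias.potential       # well-tempered FES
truth = 2.0 * (centers**2 - 1.0) ** 2
mask = np.abs(centers) < 1.35
diff = (fes - truth)[mask]
diff -= diff.mean()
print(f"deposited hills: {len(bias.hill_log)}")
print(f"FES RMSE vs analytic: {np.sqrt((diff**2).mean()):.3f} kcal/mol")
```

Output:

```
deposited hills: 999
FES RMSE vs analytic: 0.142 kcal/mol
```

999 Gaussian hills were deposited (one per 500 steps); rescaling the
accumulated bias by (T + ΔT)/ΔT and comparing with the analytic double
well over the sampled region gives a free-energy error of ~0.1 kcal/mol —
well inside chemical accuracy for this toy.

The same study is available from the shell:

```sh
colvarkit fixtures double_well_1d --out . --seed 1
colvarkit run --config double_well_1d.colvars --steps 20000 --output-prefix dw
colvarkit analyze --config double_well_1d.colvars --traj dw.xyz
```

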