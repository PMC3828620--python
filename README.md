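# dendrochem

Reaction–diffusion simulation on branched 1D cell morphologies.

Intracellular chemistry in neurons — calcium waves, second messengers,
buffering, ER/cytosol exchange — happens on dendritic trees whose geometry
matters as much as the kinetics.  `dendrochem` lets you specify such models
declaratively and integrates them with solvers that exploit the tree
structure:

* **Morphology** — branched cables built from unbranched *sections*
  (length, diameter, `nseg` finite-volume segments), programmatically or
  from SWC files.
* **Regions & geometries** — chemistry lives on cross-section subsets:
  the full cross-section, radial shells (e.g. the 90–100% submembrane
  shell), or fractional volumes for organelles like the ER; each supplies
  the volumes, longitudinal flux areas and membrane areas the solver needs.
* **Species & kinetics** — diffusible `Species`, non-diffusing `State`s and
  constant `Parameter`s combine through ordinary Python arithmetic into
  rate expressions that are compiled to vectorized evaluators and
  differentiated symbolically.  Kinetics come in three flavors: `Rate`
  (direct RHS term), `Reaction` (mass-action by default:
  `2*H + O <-> W` yields d[H]/dt = −2·kf·H²·O + 2·kb·W), and
  `MultiCompartmentReaction` (membrane-area-scaled exchange between
  compartments, optionally reporting membrane current).
* **Engine** — operator-split implicit Euler: diffusion advances by an
  O(n) tree-structured elimination (zero-volume conservation nodes at the
  section junctions), reactions by per-location linearized implicit solves
  with exact symbolic Jacobians.  A method-of-lines interface
  (`rhs_full` / `full_jacobian` / `approx_jacobian_solve`) plugs into
  scipy's adaptive stiff integrators.

Units throughout: mM, ms, µm, µm²/ms.

## The validation model

The package is validated against the scalar bistable equation

    u_t = D u_xx + u (u − α)(1 − u),        0 ≤ α < 1/2,

a minimal model of a regenerative concentration wave: sub-threshold
concentrations are cleared, supra-threshold concentrations regenerate to
the asymptote, and diffusion produces a traveling front with closed-form
speed **c = √(2D)·(1/2 − α)** on the infinite line.  Comparing the measured
front speed with this value probes every part of the pipeline at once.

## Worked example

```python
import dendrochem as dc

morph = dc.Morphology()
cable = morph.create_section("cable", L=1000.0, diam=1.0, nseg=250)  # dx = 4 µm
cyt = dc.Region([cable], nrn_region="i", name="cyt")
c = dc.Species(cyt, d=1.0, name="c",
               initial=lambda node: 1.0 if node.x <= 0.2 else 0.0)
wave = dc.Rate(c, (0 - c) * (0.25 - c) * (1 - c))

model = dc.Model(species=[c], reactions=[wave], atol=1e-13)
model.initialize()
times, states = model.run_adaptive(600.0, t_eval=[200.0, 600.0])

x = cable.arc_centers()
traj = dc.Trajectory(times, x, states[:, :250])
speed = dc.measure_wave_speed(traj, alpha=0.25)
print(f"measured {speed:.6f} µm/ms, analytic {dc.analytic_wave_speed(0.25):.6f}")
```

prints

```
measured 0.274431 µm/ms, analytic 0.353553
```

The measured speed at this coarse dx = 4 µm undershoots the analytic value
by 0.0791 µm/ms; halving dx repeatedly shrinks the error by a factor of ≈ 4
each time (0.0791 → 0.0169 → 0.0038 → 0.0009), i.e. the discretization
converges quadratically in dx.  The same study is available from the shell:

```
dendrochem validate                 # runs the α=0.25, dx ∈ {4,2,1,0.5} check
dendrochem simulate --alpha 0.25 --dx 2 -o wave.csv
dendrochem converge --alpha 0.25 --dx 4 --dx 2 --dx 1 -o table.csv
dendrochem fixtures --seed 7 --n-sections 12 -o tree.swc
```

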