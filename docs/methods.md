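# Methods

## Model structure

A model is a forest of unbranched constant-diameter cables (*sections*),
each split into `nseg` equal finite-volume *segments* whose centers sit at
normalized positions (i + 0.5)/nseg.  Chemistry is declared on *regions* —
cross-section subsets of a set of sections — and every (species, region,
section, segment) combination materializes into one node of the global
state vector.  Concentrations are mM, time ms, length µm, diffusion
coefficients µm²/ms; membrane flux in multi-compartment reactions is
molecules/(µm²·ms).

Geometries supply three quantities per segment: volume (µm³), the
cross-sectional area available to longitudinal flux at each segment
boundary (µm²), and membrane-adjacent lateral area (µm²).  The built-in
geometries are the full circular cross-section, annular shells
(lo/hi radius fractions), and fractional volumes (fraction fe of area and
volume, with independent flux-area and surface fractions).  Because the
discretization is 1D, any geometry with correct lengths, volumes and areas
produces identical dynamics; user geometries only need to implement the
three accessors.

**Surface areas of inner shells.**  There is no unambiguous convention for
the membrane-adjacent area of a shell that does not touch the outer radius;
we assign it zero, and model the conceptual boundary between adjacent
shells as a `Membrane` at the dividing radius fraction f with the area of
the dividing cylinder, π·f·d·L/nseg.

## Rate expressions

Arithmetic on species/state/parameter handles builds expression trees;
nothing is evaluated at build time.  Trees are compiled by serializing them
to a canonical fully-parenthesized string with stable reference ids and
byte-compiling that string into a numpy lambda, so evaluation is one
vectorized pass over all active locations.  The unary math catalog (log,
exp, sin, cos, tan, sinh, cosh, tanh, sqrt, log10, fabs) is extensible at
runtime by registering (name, evaluator, derivative) triples.

Jacobians are obtained by symbolic differentiation of the same trees
(standard product/quotient/chain/power rules with light constant folding);
finite differences are used only as an independent oracle in the tests.
Reactant schemes (`2*hydrogen + oxygen`) are validated into maps of
positive integer coefficients; integer multiplication distributes exactly
over sums (`2*(h+o)` ≡ `2*h+2*o`), but no other algebra is applied — a
reaction scheme is not an equation, so `4*h+2*o` is deliberately a
different scheme from `2*h+o`.  A constant counts as an integer when it is
within 1e-9 of one.

Division by zero during evaluation produces the platform inf/NaN and a
logged warning; non-finite states make the implicit step fail and trigger
the dt-halving retry.

## Kinetics

* `Rate(target, expr)` adds `expr` verbatim to the target's RHS (mM/ms for
  species, 1/ms for unitless states).
* `Reaction(lhs, rhs, kf, kb)` with mass action uses flux
  kf·Π s^n − kb·Π p^m and per-species contribution (dest − source
  multiplicity)·flux; with `mass_action=False`, kf and kb are the full
  forward/backward rates.
* `MultiCompartmentReaction` requires region-qualified references and a
  membrane.  Its flux f carries molecules/(µm²·ms); compartment k receives
  dc_k/dt = ±m·f·A/V_k·U with membrane area A, compartment volume V_k, and
  U = 1/602214.129 converting molecules/µm³ to mM (1 mM ≡ 6.02214×10⁵
  molecules/µm³).  With `scale_by_area=False` the area factor is 1 and f is
  interpreted per-location rather than per-area.  For the default
  mass-action case the rate constants absorb the concentration powers:
  kf has units molecules·µm^(3n−2)·mM^(−n)/ms for total source multiplicity
  n.  This convention is dimensionally consistent and tested as such; it is
  a documented package choice, kept in two named constants so a different
  convention is a one-line change.
* With `membrane_flux=True` every crossing species must declare an integer
  charge, and the reaction reports an outward-positive current density
  i = Σ z·m·f × 1.602177×10⁻⁵ mA/cm² per unit molecular flux (elementary
  charge × ms→s × µm²→cm² × A→mA).  The current is an observable only;
  feedback into a membrane-potential equation is out of scope.  The outward
  side is the compartment not tagged `nrn_region='i'`; if neither side is
  tagged, the source side is taken as inward.

Reactions localize by default to every region hosting all of their state
variables; an explicit `regions=` overrides this.

## Numerical integration

**Diffusion.**  Longitudinal diffusion discretizes as V_i dc_i/dt =
Σ g_ij (c_j − c_i) with conductance g = D·A/Δx between adjacent segment
centers (Δx = L/nseg inside a section).  Section ends meet at explicit
zero-volume *conservation nodes*: the algebraic row Σ g (c_nb − c_j) = 0
forces zero net flux through each junction, and the coupling between a
junction and the adjacent segment center uses the boundary area and the
half-segment distance Δx = L/(2·nseg).  Outer boundaries are sealed
(zero flux).  The implicit-Euler system

    (V_i + dt Σ g) c_i − dt Σ g c_j = V_i c_i^old   (volume rows)
    Σ g c_j − Σ g c_nb = 0                          (junction rows)

has tree-structured sparsity when rows are ordered parent-before-child
(depth-first from the roots): each row couples only to its parent, so one
leaf-to-root elimination and one root-to-leaf substitution solve it exactly
in O(n).  The matrix is asymmetric — volume rows carry the factor dt while
junction rows do not, and entries depend on the local volumes.  Junction
rows sum to zero by construction; since they are algebraic the junction
entries are recomputed flux-consistently (c_j = Σ g c_nb / Σ g) whenever a
solver path bypasses them.  Implicit Euler on this M-matrix preserves
non-negativity and conserves Σ V_i c_i exactly.

**Reactions.**  Per time step, one linearized implicit-Euler (single
Newton) solve per spatial location: (I − dt·J)Δc = dt·r(c), with J the
exact symbolic reaction Jacobian.  Blocks touching only their own variable
solve in a vectorized scalar pass; coupled blocks go through a sparse LU of
the block-diagonal system.  Because the per-compartment scale factors are
±m·A·U/V_k, the volume-weighted row sums of both r and J vanish, so
multi-compartment transfer conserves moles exactly per step (to rounding),
independent of dt.

**Operator splitting.**  `advance(dt)` performs exactly one diffusion step
followed by one reaction step; the splitting error vanishes linearly as
dt → 0 (measured self-convergence order ≈ 0.9–1.0 on the bistable model).
A failed step (singular block, non-finite update) rolls back and retries as
two half steps, up to 10 halvings, then aborts with node diagnostics.
Negative concentrations are never clamped; a diagnostic warning is logged
when any state drops below −10·atol, since clamping would mask integration
errors.

**Adaptive integration.**  The model also exposes a method-of-lines
contract: `rhs_full` (diffusion with junctions eliminated by the Schur
complement — exactly equivalent to the conservation rows — plus reaction
terms), `full_jacobian` (sparse), and `approx_jacobian_solve(γ, b)`, the
split approximation that tree-solves the diffusion factor and then applies
the cached reaction-block factorizations (refreshed only via
`refresh_jacobian`, mirroring how adaptive integrators request Jacobian
updates; the approximation can shrink accepted steps but adds no error to
converged solutions).  The bundled driver `run_adaptive` delegates to
scipy's BDF integrator; scipy's BDF accepts an explicit sparse Jacobian
rather than a linear-solve callback, so the driver supplies
`full_jacobian` directly and `approx_jacobian_solve` remains available for
integrators with preconditioner hooks.  Re-implementing a variable-order
stiff integrator is explicitly out of scope.

## The bistable validation study

`BistableScenario` defaults define the study conditions: a single cable of
L = 1000 µm and diameter 1 µm, D = 1 µm²/ms, kinetics rate
(0 − c)(α − c)(1 − c), and initial condition c = 1 on the leftmost 200 µm,
c = 0 elsewhere.  The seed width and cable length were chosen once so that
the front is fully developed by t = 200 ms and stays ≥ 50 µm clear of the
far boundary at t = 600 ms for every α ∈ [0, 0.49); a post-hoc boundary
check flags violations in the trajectory metadata.  Concentrations are
dimensionless multiples of the asymptotic value (the rate form pins the
stable states at 0 and 1).

The front position is the rightmost linearly-interpolated downward crossing
of c = α (nearest-grid-point measurement would alias at coarse dx), and the
wave speed is the average front displacement between t = 200 and 600 ms.
The adaptive solver runs at absolute tolerance 1e-13 with relative
tolerance 1e-7; at these settings the measured speed is converged in time
to < 1e-4 relative, so the reported error is the spatial discretization
error.  At α = 0.25 the absolute speed error versus √(2D)(1/2 − α) is
0.0791, 0.0169, 0.0038 and 0.00093 µm/ms at dx = 4, 2, 1, 0.5 µm — a
reduction by a factor of ≈ 4 per halving, i.e. quadratic spatial
convergence.

## What the synthetic fixtures do and do not show

`random_tree_morphology` generates connected random trees (uniform parent
choice, uniform section dimensions) used for the solver oracles and
conservation suites.  These exercise arbitrary branching topology, unequal
volumes, and junction conservation, but not real morphometry (diameter
tapering and correlations, spines), multi-species signaling networks at
realistic rate constants, or electrical coupling — passing tests demonstrate
correctness of the numerics, not biological realism of any particular
model.

## Problem sizes and numerical choices

* Test-suite simulations use cables of 25–2000 segments and trees of up to
  ~20 sections; the convergence study runs the full 250–2000-segment
  cables.  The splitting-order measurement uses L = 200 µm, dx = 2 µm,
  T = 20 ms at dt = 0.2, 0.1, 0.05 ms — inside the asymptotic first-order
  regime.
* Tree elimination flags an exactly-zero pivot as singular and names the
  offending node; junction rows of non-diffusing species are set to
  identity to keep the cached matrices nonsingular.
* The expression compiler treats structurally equal trees as identical via
  their canonical serialization; no algebraic simplification is performed
  beyond constant folding in derivatives.
* SWC import groups points into one section per unbranched path, breaking
  also at type-code changes (all types are otherwise treated as plain
  cable); diameters average the path's own points, excluding an inherited
  branch point.  The mirrored export writes one straight edge per section
  with alternating type codes so section boundaries survive round trips;
  per-section `nseg` does not (SWC has no discretization concept).

## Known limitations

* Constant diameter per section; no tapering, spines, or 3D/stochastic
  discretization.
* No membrane-potential coupling: currents from `membrane_flux=True` are
  observables only.
* The fixed-step reaction solve is a single Newton iteration per step
  (first-order consistent); strongly stiff kinetics rely on the dt-halving
  retry or the adaptive driver.
* The multi-compartment mass-action unit convention is documented above
  rather than being guaranteed to match any other simulator's internal
  constant.
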