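# Methods

## Model and assumptions

The tissue served by one blood vessel is idealized as a cylindrically
symmetric annulus: inner radius r_b (the vessel wall), outer radius
r_b/BVF, where the blood volume fraction BVF sets how much tissue each
vessel supports.  All fields depend on radius r and time t only; there
is no axial or angular structure, no immune response, and no healthy
tissue compartment — the domain is tumor throughout.

Three (Phase I) or four (Phase II) species react and diffuse:

* `x` — uninfected tumor cells.  Aggressive exponential growth at rate
  r₁ (no carrying capacity over the 30-day horizon), slow random
  motility D₁.
* `y` — virus-infected tumor cells, produced by mass-action infection
  βxv, dying by lysis at rate δ.
* `v` — free virus, produced by lysis with burst size b, consumed on
  infection (κ virions per infected cell; κ = 1 since one virion
  suffices to infect one cell) and cleared at rate α.
* `u` — radiation-damaged cells (Phase II only), fed from x and y at
  rates a₁R(t) and a₂R(t), removed at rate γ.  Damaged cells are
  immotile: the u equation has no diffusion term and therefore needs
  no boundary condition.

Boundary conditions: no-flux for x and y at both boundaries; virus is
clamped to the delivery concentration v₀ at the vessel wall for the
whole simulation (continuous administration through the vasculature)
and no-flux at the outer rim.  With radiation off, the Phase II
equations reduce exactly to Phase I plus a decoupled, decaying u — the
test suite asserts this node-for-node.

## Parameters

Defaults (hours, millimetres, per-mm³ densities):

| name  | meaning                                | default | units |
|-------|----------------------------------------|---------|-------|
| D1    | tumor-cell diffusivity                 | 1e-8    | mm²/h |
| r1    | tumor growth rate                      | 0.02    | 1/h   |
| beta  | viral infection rate                   | 7e-10   | mm³/(h·virion) |
| delta | infected-cell lysis rate               | 1/18    | 1/h   |
| D2    | virus diffusivity                      | 5e-7    | mm²/h |
| b     | burst size                             | 50      | virions/cell |
| kappa | virions consumed per infection         | 1       | virion/cell |
| alpha | virus clearance rate                   | 0.008   | 1/h   |
| a1,a2 | radiation damage rates (x, y)          | 0.01    | 1/h per dose-rate unit |
| gamma | damaged-cell death rate                | 0.01    | 1/h   |
| r_b   | vessel radius                          | 0.01    | mm    |
| BVF   | blood volume fraction                  | 0.05    | —     |
| v0    | virus density at the vessel wall       | 0.5e6   | virions/mm³ |
| x0    | initial uninfected density             | 0.5e6   | cells/mm³ |
| t_r   | radiotherapy start time                | 120     | h     |

Rate-like parameters may be set to zero to switch a process off (the
well-mixed limit D1 = D2 = 0, the no-virus control v0 = 0, the
conservation checks r1 = β = δ = α = 0); geometry and x0 must stay
positive, and 0 < BVF < 1.

Radiation schedules measure time from t_r, since no radiation exists
before Phase II; with that convention the constant and decaying
defaults agree (R = 2) at the moment radiation starts, which is the
intended behaviour of the protocol comparison.  The periodic argument
ω and decay exponent α₁ are taken per hour, consistent with the
solver clock; default schedules are R = 2 (constant),
2·e^(−0.01(t−t_r)) (decay) and 1 + sin 2(t−t_r) (periodic).  The
periodic offset must dominate the amplitude (β₂ ≥ |α₂|) so the dose
rate never goes negative.

## Initial conditions

`x(r,0) = x0` uniform and `y(r,0) = 0` (no infected cells before
treatment).  The initial virus profile is a genuine modelling choice
with two defensible readings, both implemented:

* `initial_virus="uniform"` (default): v(r,0) = v₀ throughout the
  annulus — the delivery mechanism (e.g. nanovectored carriers) has
  distributed virus through the tissue by t = 0.
* `initial_virus="wall"`: v(r,0) = 0 except v = v₀ at the wall — virus
  enters only by diffusion from the vessel.

The uniform default is the physically coherent one for this parameter
set: with D₂ = 5e-7 mm²/h the diffusive crossing time of the 0.19 mm
annulus is ≈ 7·10⁴ h, so wall-sourced virus cannot reach most of the
tissue within the 720 h treatment window at all; infection then spreads
only as a slow amplification wave that takes ~13 days to ignite.
Under the uniform profile the viral takeover of the growing tumor
happens shortly before day 6, radiation from day 5 interacts with an
established infection, and the Phase II schedule comparison behaves as
intended (see "Known discrepancies").

## Discretization and integration

* Uniform node-centred grid on [r_b, r_b/BVF]; default 191 nodes
  (dr = 0.001 mm), which resolves the viral penetration boundary layer
  sqrt(D₂/(κβx₀+α)) ≈ 0.008 mm with ~8 nodes.
* Cylindrical Laplacian (1/r)(r f′)′ by second-order central
  differences.  No-flux boundaries use a flux-form half-cell closure:
  the discrete flux through the boundary face is exactly zero, so a
  diffusion-only run conserves the trapezoid-quadrature mass
  Σ wᵢ rᵢ fᵢ to roundoff (the plain mirrored-ghost-node closure leaks
  mass at a few parts in 10⁶ per 100 h, which would mask real
  conservation bugs in tests).  Clamped (Dirichlet) nodes report a zero
  Laplacian; their time derivative is suppressed.
* Classic fixed-step RK4 in time.  The virus wall node is re-clamped
  to v₀ before every stage evaluation and after every full step, so
  the boundary value is exact at stage points.  The integrator refuses
  to start if dt exceeds the explicit-diffusion comfort bound
  0.25·dr²/max(D₁,D₂) (0.5 h at default resolution) and aborts with
  the step index if any field becomes non-finite.
* Default dt = 0.05 h.  Time discretization error is negligible at
  this setting: f_x(720 h) agrees to 10 significant digits between
  dt = 0.1, 0.05 and 0.025, comfortably inside the design rule that
  halving dt must move f_x(t_end) by < 0.1%.  Accuracy is limited by
  the spatial grid, not the time step.
* Snapshots every 1 h by default (so timing claims are resolvable to
  the hour), always including t = 0 and t_end.

Two-phase runs integrate Phase I to t_r, append u = 0, and continue
with the radiovirotherapy right-hand side.  The stored record switches
phase label exactly at t_r; the Phase II segment of f_x is rebased to
the viable mass present at t_r so both arms of a comparison start
at 1.

## Output metrics

f_x(t) is computed by composite trapezoid quadrature of 2π·x·r on the
grid nodes.  Trapezoid is exact for the linear integrand of a uniform
field, so f_x(0) = 1 holds exactly, and its O(dr²) error matches the
spatial scheme.  Trajectory summaries report the global minimum,
maximum and endpoint at snapshot resolution (no interpolation).
Oscillation detection ignores extrema whose prominence is below 1% of
the trajectory range (quadrature/time-cadence jitter); "eradicated"
means f_x < 0.01 at t_end and non-increasing over the final 48 h.
These two thresholds are labelling conventions for summaries only and
never feed back into the dynamics.

## Verification strategy

Every nontrivial numerical component is checked against an
independent oracle in the test suite:

* β = 0 → f_x(t) = e^(r₁t) exactly (closed form), to 1e-6 relative.
* D₁ = D₂ = 0 with uniform fields → the PDE collapses to an ODE
  system, compared snapshot-by-snapshot with an adaptive high-accuracy
  `solve_ivp` integration, to 1e-4 relative.
* x = y = 0 → the virus field relaxes to the steady profile of
  D₂∇²v = αv with the wall clamp, compared with a direct linear solve
  of the same discrete operator.
* All reactions off, all boundaries no-flux → per-species mass
  constant to 1e-6 relative over 100 h.
* Grid refinement n = 96 → 191 → 381 gives an observed convergence
  order ≈ 2 for f_x at a 240 h horizon.  The 720 h endpoint is *not*
  suitable for convergence measurement: it sits on a
  suppressed-regrowth branch whose position shifts non-smoothly
  between grids, producing spurious ratios.

Problem sizes in the test suite (41–96 nodes, 24–240 h horizons for
oracle checks; full 191-node 720 h runs for the trajectory-landmark
checks) were chosen so each check isolates one mechanism at the
smallest scale where it is meaningful.

## Known discrepancies and limitations

The acceptance suite checks the simulated trajectories against
reference landmarks for this treatment scenario: Phase I trough ≈ 7%
and 30-day endpoint ≈ 55% of initial mass, viral takeover near day 7,
and Phase II suppression to ≈ 1% of the radiation-start baseline after
6 days of constant R = 2.  At converged resolution this implementation
reproduces the Phase II landmark (0.04%, within the ±3-percentage-point
band), the qualitative schedule ordering (constant ≤ periodic ≤
decaying at end of run, regrowth under decaying delivery), and the
parameter-sensitivity directions (deeper/earlier control with larger
β, more residual tumor with larger α, loss of oscillation at b = 2).

It does **not** reproduce the Phase I trough/endpoint pair: the
default run bottoms at ≈ 1.2% and ends at ≈ 7.5%.  No grid between 10
and 571 nodes, neither initial-virus profile, nor the well-mixed ODE
limit yields 7%/55% with these rates: after the viral takeover the
virus population overshoots to ~10⁹/mm³ and, clearing at only
α = 0.008/h, suppresses regrowth well past day 30.  A rebound to 55%
by day 30 would require a much milder overshoot than b = 50 and
δ = 1/18 produce.  (The well-mixed coexistence state of the system is
f_x* = 0.466, so a ≈ 55% quasi-plateau is reachable — but only on a
longer horizon or with unconverged spatial resolution; a ~39-node grid
happens to reproduce the 7% trough but then loses containment
entirely.)  The defaults stay at converged resolution and the
discrepancy is reported rather than tuned away.

Other limitations: purely radial geometry; no resistance, immune
clearance or healthy-tissue toxicity; radiation acts only through the
damage compartment (no direct synergy with infection); the constant
dose R = 2 exactly cancels r₁ (a₁R = r₁), so conclusions about
"constant radiation eradicates" are tied to that balance; sweep
legends (the β/b/α value lists and the constant-dose levels {1, 2, 4}
in the timing×dose figure) are package choices and not validated
reference values.
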