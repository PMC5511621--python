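# Methods

## The model

`morphograft` simulates the long-term contraction of a skin graft placed on
an excised burn. The dermal layer is treated as a heterogeneous, isotropic,
morphoelastic visco-elastic solid coupled to four constituents: fibroblasts
N, myofibroblasts M, a generic signaling molecule c (TGF-β is the
prototype), and collagen ρ. Because contraction is in-plane, the problem is
reduced to an infinitely thin slice parallel to the skin surface: the
out-of-plane displacement, velocity and strain components vanish
identically, and all tensors are stored by their in-plane components
(t22, t23, t33), with traces taken over those components.

Three balance laws govern the slice, all written in Lagrangian (material)
form:

- **Constituent balance.** Dz/Dt + z ∇·v = −∇·J_z + R_z for each
  constituent z. Cells disperse with a density-dependent motility
  D_F (N+M) ∇z and chemotax up the signal gradient (χ_F z ∇c); the signal
  diffuses Fickianly (D_c); collagen does not move (J_ρ = 0).
- **Momentum balance.** ρ_t Dv/Dt + ρ_t v (∇·v) = ∇·σ + ∇·ψ, with the
  visco-elastic stress σ = μ₁ sym L + μ₂ tr(sym L) I +
  [E(ρ)/(1+ν)] {ε + tr ε · ν/(1−2ν) · I}, the collagen-dependent stiffness
  E(ρ) = E_I √ρ, and the isotropic myofibroblast traction
  ψ = ξ M ρ/(R² + ρ²) I.
- **Strain evolution (morphoelasticity).** The effective strain
  ε = I − A⁻¹ measures the gap between the current and the locally
  stress-free configuration. Its Jaumann rate obeys
  𝒟ε/𝒟t + [tr ε − 1] sym L = −G with the growth tensor
  G = ζ (N + η_II M) c / (1 + a_c_III c) · ε. While the signal is present,
  G erodes the effective strain *in place*: the stress-free configuration
  creeps toward the deformed one, which is precisely how a contracture —
  a permanent deformation surviving the disappearance of the contracting
  cells — arises. With ζ = 0 the deformation is fully recoverable.

The reaction kinetics are Hill-saturated: division of N and M is enhanced
by c and limited by crowding (factor 1 − κ_F(N+M) on a power N^{1+q});
fibroblasts differentiate into myofibroblasts at rate k_F c N;
myofibroblasts apoptose at δ_M. The signal is secreted by both cell types
(weighted η_I) and destroyed by MMPs; MMP activity is not a state variable
but the derived level g = (N + η_II M) ρ / (1 + a_c_III c), so the signal
inhibits its own protease. Collagen is secreted (enhanced by c) and
degraded by the same MMP level.

## Geometry, initial and boundary conditions

The computational domain is the square slice [−10, 10]² cm. The graft is a
square of half-side s1 = 2.5 cm rotated by θ_r = π/4, described by a smooth
indicator w ∈ [0, 1] (0 = grafted dermis, 1 = unwounded dermis) built from
one-sided sinusoidal ramps of half-width s2 = 0.1 cm. A naive product form
of the indicator evaluates to 1 at the graft center, contradicting the
intended meaning; the package therefore uses the form w = 1 − B(Y_r)B(Z_r) with the bump B(r) = [1 − I(r, s1, s2)]·
I(r, −s1, s2), which is 0 at the center, 1 in the far field, and even in r.

Initial conditions: N = {I_w + (1−I_w) w} N̄ (a fraction I_w = 0.2 of
fibroblasts survives grafting), M = M̄ = 0, c = (1−w) c_w (inflammatory
signal confined to the graft), ρ = ρ̄, and u = v = ε = 0. Boundary
conditions: Dirichlet N = N̄, M = M̄, c = c̄ for the constituents and v = 0
for the velocity (the far field is mechanically held, as under splinting).
Collagen carries no boundary condition since it has no flux.

Graft area is tracked by material tracer points on the graft boundary
square (corners plus, by default, edge midpoints); the reported relative
area is the shoelace area of the displaced tracer polygon over its
reference area (25 cm² for the default geometry).

## Parameters

All quantities are dimensional (cm, day, g, cells). The packaged defaults
(`morphograft/data/default_parameters.toml`) follow the magnitudes used
across the published model family this simulator belongs to; every value
can be overridden from TOML or keyword arguments. Two constants define the
reference contracture scenario: ζ = 9×10² cm⁶/(cells g day) and
a_c_III = 2×10⁸ cm³/g. The four constants that control the
amplitude and duration of the healing episode (k_F = 3×10⁶ cm³/(g day),
δ_c = 8×10⁻⁴ cm⁶/(cells g day), k_c = 4×10⁻¹³ g/(cells day), δ_M = 6×10⁻²
/day) were fixed once against the homogeneous reduction so that the
simulated arc is physiologically plausible: myofibroblast peak ≈ 13% of N̄
near day 22, signal cleared by ≈ day 35, collagen overshoot ≈ 1.7×,
traction peak ≈ 80 N/cm². The total tissue density ρ_t = 1.02 g/cm³
(typical soft tissue; it only scales the negligible inertial terms).

Dependent parameters: the unwounded state (N̄, M̄, c̄, ρ̄) must be a fixed
point of the reaction system. With the standard choice M̄ = c̄ = 0 the
myofibroblast and signal balances vanish identically (every term carries a
factor M or c), leaving two active constraints solved in closed form:
δ_N = r_F (1 − κ_F N̄) N̄^q and k_ρ = δ_ρ ρ̄². The
`derive_equilibrium_parameters` API accepts any unknown set (≤ 3) and
falls back to a least-squares Newton solve, rejecting over- or
under-determined combinations; completion is verified to residuals
< 10⁻¹⁰ in the equations' natural units and is idempotent.

## Numerics

**Moving grid.** Linear (P1) triangles on a uniform criss-cross mesh of the
square, moved with the material velocity (u is added to the reference
coordinates after every accepted step). On such a Lagrangian grid the weak
form of the constituent balance reduces to d/dt ∫ z φ = ∫ J·∇φ + ∫ R φ: no
discrete advection term appears and the dilution term z ∇·v is carried
exactly by the difference between the mass matrices of the old and the
moved configuration. A rigid translation therefore transports nodal values
exactly, which the suite asserts to 10⁻¹⁰.

**Positivity.** Each transport update combines (i) a low-order solve with
lumped mass and algebraic artificial diffusion D_ij = max(0, −K_ij, −K_ji)
(an M-matrix, hence non-negative), (ii) a high-order Galerkin solve with
consistent mass, and (iii) a Zalesak limiter on the antidiffusive edge
fluxes f_ij = −MC⁰_ij(z⁰_i − z⁰_j) + (MC¹_ij + Δt D_ij)(z^H_i − z^H_j),
which restores high-order accuracy wherever that cannot push a node past
the local low-order bounds. The correction is conservative (antisymmetric
fluxes) and never creates negative values. Reactions are split à la
Patankar into non-negative production (explicit) and a non-negative loss
rate treated implicitly, so the reaction update preserves positivity
unconditionally.

**Mechanics coupling.** The momentum solve is semi-implicit: viscosity and
the first-order elastic stress increment σ_el(Δt sym ∇v^{n+1}) are
implicit (this removes the fast visco-elastic relaxation mode, time
constant ≈ μ/E ≈ 1 day, from the stability budget), while the current
elastic stress, the traction force (integrated by parts, with the boundary
term dropped where v is constrained) and the tiny advective term are
explicit. Strain is then advanced explicitly with the Jaumann-corrected
rate, using a lumped projection of ∇v to the nodes. Nonlinear coefficients
are Picard-lagged at the start of the step.

**Time adaptivity.** Step-doubling: each attempted step is computed once
with Δt and once as two Δt/2 steps; the maximum relative discrepancy over
constituents, displacement and strain (velocity is slaved and excluded) is
compared with the tolerance (default 10⁻³). Accepted steps keep the
half-step result and may grow Δt by at most 1.5×; rejected steps halve Δt;
underflow below Δt_min aborts with a diagnostic. Errors exactly at
tolerance are accepted.

**Adaptive resolution.** Longest-edge (Rivara) bisection with recursive
conformity propagation, genealogy bookkeeping, and recoarsement of sibling
pairs whose midpoint star is fully coarsenable; state transfers by linear
interpolation (exactly mass-conservative under refinement), with a lumped
redistribution restoring the constituent integrals after recoarsement.
Default scenarios run on a uniform mesh: the convergence check below shows
the desk-scale resolutions already capture the area dynamics to within a
fraction of a percent, and a static grid keeps the symmetry analysis and
runtime predictable; refinement is exercised by its own tests and enabled
through `ScenarioConfig.refine_every`.

**Problem sizes.** Scenario runs use target edge 1.25 cm (289 nodes, 512
triangles; 1 cm for exploratory runs), horizons of 150 days for the ζ = 0
recovery, 365 days for the contracture run (the late-time stationarity
claim concerns day ~219 vs 365), 120 days for sweeps, and 30 days for the
equilibrium control. These sizes keep every scenario in the low minutes on
one CPU while leaving all qualitative outcomes stable: halving the target
edge changes the day-50 relative area by under 2%.

## Validation strategy

The independent oracle is the spatially homogeneous reduction (all
gradients and velocities zero): plain reaction ODEs plus the scalar strain
law de/dt = −ζ k e, k = (N + η_II M) c/(1 + a_c_III c), integrated with a
generic stiff solver (LSODA, rtol ≤ 10⁻¹⁰) — an entirely separate
numerical path from the FEM engine. On spatially uniform fields with
natural boundary handling the FEM solution must coincide with the ODE
trajectory; the suite requires max relative deviation < 10⁻³ (measured
6.5×10⁻⁴ at the default controller tolerance of 5×10⁻⁶ used for this
comparison). Frozen-kinetics strain decay is checked against the closed
form e₀ e^{−ζkt} to 10⁻⁸, and the FCT limiter against a brute-force
search over admissible flux fractions on a 3-node fixture.

What the homogeneous oracle does not probe: spatial coupling (diffusion,
chemotaxis, mechanics) and the moving grid. Those are covered by
construction-level tests (translation exactness, conservation to 10⁻⁸ over
100 steps, uniform-traction rim identity, point-reflection symmetry to
10⁻⁸ over full runs) rather than by an external reference solution, which
does not exist in closed form for this model.

## Interpretation choices and limitations

- *Late-time stationarity.* The residual-stress persistence check compares
  the area-weighted L2 Frobenius norm of the strain field at 60% and 100%
  of the horizon (< 5% change). A pointwise difference norm keeps moving
  longer because collagen — and with it the local stiffness E = E_I √ρ —
  relaxes on a ≈ 140-day timescale, re-balancing the small residual strain
  field while its magnitude stays put.
- *"Final" sweep readout* is the value at end time, not the trajectory
  minimum: the end value is the contracture measure.
- The traction amplitude and kinetic defaults reproduce a plausible arc,
  not a fitted patient trajectory; clinical contraction curves are
  deliberately out of scope.
- The finite-strain variant of the strain evolution and anisotropic
  collagen-bundle mechanics are not implemented; the infinitesimal
  effective-strain law is only trustworthy while |ε| stays moderate (the
  default scenarios peak near 0.35).
- The momentum equation retains inertial terms by default although they
  are ~10 orders of magnitude below the stress terms at these scales;
  `quasi_static=True` drops them and agrees to < 10⁻³ in velocity.
- Mass redistribution after recoarsement is global (uniform per unit
  lumped mass); with the default coarsening policy (only where fields are
  nearly flat) the correction is at round-off level.
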