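# Methods

This note records the model equations as implemented, the provenance of every
parameter, the numerical design choices, and the limitations we measured.

## 1. The local-density potential

The potential energy of a configuration of N identical particles in a
periodic box is

```
U = Σ_i a_ex(ρ̄_i) + (κ/2) Σ_i |∇ρ̄_i|²,
ρ̄_i = Σ_{j≠i} w(r_ij),          ∇ρ̄_i = Σ_{j≠i} w'(r_ij) r̂_ij,
```

with `r̂_ij` the unit vector from j to i.  `a_ex(ρ)` is the excess (over
ideal) Helmholtz free energy per particle of the input equation of state,
evaluated at the particle's own smoothed density.  In a large homogeneous
system `ρ̄_i → ρ_bulk` and `U/N → a_ex(ρ_bulk)`, so bulk thermodynamics of the
model fluid reproduces the input equation of state up to fluctuation effects
quantified in §6.  The self term is excluded from `ρ̄_i`: an isolated particle
has zero excess energy, which keeps the dilute limit exactly ideal.

The weighting function is the Lucy kernel

```
w(r) = 105/(16 π r_c³) (1 + 3r/r_c)(1 − r/r_c)³   for r < r_c, else 0,
```

normalized to unit three-dimensional integral, with `w'(r_c) = 0` so both the
density field and its gradient are continuous as neighbors cross the cutoff.
The cutoff convention is `r_c = 4σ(T)` with σ the Mie diameter (or the
covolume-equivalent diameter `b = (2π/3)σ³` for the van der Waals backend).

The square-gradient term adds interfacial stiffness: in a bulk phase the
gradients are small fluctuations, at an interface they are large and
systematic, so κ (units K nm⁸) raises the surface tension approximately
linearly while perturbing bulk states only weakly (§7).

## 2. Equation-of-state backends

`a_ex` in kelvin as a function of (ρ in nm⁻³, T in K):

- **ideal**: `a_ex = 0`.
- **vdw**: `a_ex = −T ln(1 − bρ) − aρ` with a = 67.63 K nm³ and
  b = 0.03097 nm³, chosen so the critical point matches water
  (T_c = 647.1 K, ρ_c = 322 kg/m³).  Pressure, chemical potential and
  compressibility have closed forms, which makes this the oracle backend for
  testing.
- **associating**: `a_ex = a_mono + a_assoc` (no chain term; the molecule is
  a single sphere).

**Monomer term.** Third-order Barker–Henderson perturbation theory for Mie
fluids: temperature-dependent hard-sphere diameter
`d(T) = ∫₀^σ [1 − e^{−φ_Mie(r)/T}] dr` (64-point Gauss–Legendre), the
Carnahan–Starling hard-sphere free energy, and first/second/third-order
attractive corrections built from correlation-integral fits (effective
packing fraction for each Mie exponent, the standard 4×4 coefficient matrix,
and the 6×7 rational-function matrix for the fluctuation term).  So
`a_mono = T·a_HS + a₁ + a₂/T + a₃/T²` in our kelvin units.  Parameters for
water: ε/k_B = 266.68 K, σ = 0.30063 nm, λ_r = 17.02, λ_a = 6.

**Association term.** Wertheim first-order perturbation theory for a
four-site (2 donor + 2 acceptor) model.  The fraction X of sites not bonded
solves `X = 1/(1 + 2ρΔX)` in closed form, and

```
a_assoc = T [ 4 (ln X − X/2) + 2 ],
Δ = K_AB [e^{ε_HB/T} − 1] g_HS(d; η),    g_HS = (1 − η/2)/(1 − η)³.
```

The bond-strength closure uses the hard-sphere contact value.  The published
parametrization of this water model uses a different (tabulated-polynomial)
closure whose coefficients are not available to us, so (ε_HB, K_AB) were
**re-fitted under our closure** against standard water saturation data
(liquid density and vapor pressure, 300–550 K) *before any simulation test
was written*: ε_HB = 1816.2 K, K_AB = 1.4352 × 10⁻³ nm³.  The resulting
equation of state reproduces the saturation pressure to about 4% and the
liquid density to about 4% (slightly flat liquid branch) over that range.
The temperature-dependent Mie parametrizations used for dedicated VLE/IFT
studies are shipped only as structurally-valid placeholders flagged
`provenance = "placeholder"`; no shipped result depends on them.

## 3. Monte Carlo engine

Metropolis sampling in NVT (single-particle displacements) and NpT
(displacements plus ln V volume moves with isotropic rescaling, acceptance
`exp{−[ΔU + pΔV − (N+1)T ln(V′/V)]/T}`).  Displacement moves update `ρ̄` and
`∇ρ̄` incrementally — a move of particle i touches only neighbors within
`r_c` of its old or new position — giving O(N) cost per move with exact
bookkeeping; the cached energy is verified against a from-scratch
recomputation during and at the end of every run (tolerance 10⁻⁶ relative,
violation raises).  Step sizes adapt toward 35% acceptance during
equilibration only and are frozen for production, so the sampled distribution
is unbiased.  A run is bit-reproducible given (protocol, seed).

`a_ex(ρ)` is evaluated from a 4001-point cubic-spline lookup table.  Beyond
the tabulated range the table continues *linearly* with the end slope: cubic
extrapolation can turn over and fabricate an attractive well at high density,
which destabilizes the simulation; linear continuation keeps the effective
free energy convex there.  Out-of-range evaluations are counted and reported.

## 4. Measurements

- **Density profile / coexistence**: z-histogram averaged over frames; a
  hyperbolic-tangent slab profile is fitted, and coexistence densities are
  plateau averages over bins beyond the 1–99% interface bounds (the 10–90
  bound, which defines the reported interface width, still carries ~1%
  interface density and would bias the plateaus).
- **Test-area surface tension**: ghost (never accepted) volume-preserving
  deformations of every frame, `(L_x, L_y) → √(1±ξ)`, `L_z → 1/(1±ξ)`;
  `γ = (ΔA₊ − ΔA₋)/(4 ξ L_x L_y)` with `ΔA_± = −T ln⟨e^{−ΔU_±/T}⟩`,
  ξ = 5×10⁻⁴ by default.
- **Test-volume pressure**: ghost rescaling by (1±ζ) along one axis;
  `p_± = (T/±ΔV)[N ln(V′/V) + ln⟨e^{−ΔU_±/T}⟩]`, central average, ζ = 10⁻⁴.
- **Isothermal compressibility**: NpT volume fluctuations,
  `β_T = Var(V)/(T⟨V⟩)`.
- Scalar series are summarized by 20-block block averaging.

## 5. κ calibration

γ(κ) is measured on a slab over a κ grid, fitted by weighted least squares to
`γ = a + bκ`, and inverted for the κ* that meets a target surface tension.
R² < 0.98 flags a non-linear response; a non-positive slope is an error.  A
state-dependent κ(T) is represented by a low-order polynomial through
per-temperature calibrations, valid only inside the fitted range.  On a van
der Waals slab at 0.70 T_c (N = 1000) the response is linear to R² ≈ 0.998
and a held-out κ is recovered within ~1.3 combined standard errors.

## 6. Known limitation: finite-r_c pressure bias

Because the energy is `Σ a_ex(ρ̄_i)` rather than `N a_ex(ρ)`, fluctuations of
`ρ̄` couple to the curvature of `a_ex` and shift the *absolute* pressure of
the model fluid away from the input equation of state by roughly
`ρ ∂²a_ex/∂ρ² Var(ρ̄)/2` per particle.  The bias vanishes as `r_c` grows
(more neighbors average the fluctuations away): for the van der Waals liquid
at ρ = 25 nm⁻³, T = 550 K we measured deviations of −16.8%, −11.6% and −7.8%
at `r_c/σ` = 3, 4 and 5.  At vapor-side densities the bias is small (−2.2% at
ρ = 2 nm⁻³, the bulk-consistency check in the test suite), and at stiff
water-like liquid states the *density* error implied by the pressure offset
is ~1% because `∂p/∂ρ` is enormous there.  Derivative properties are cleaner
than absolute ones: an NVT-measured pressure fed back into an NpT run
reproduces the NVT density to 0.05%.  Consequences for the test suite: bulk
EoS consistency is asserted at a vapor-side state, and liquid-state engine
consistency is asserted as an NVT↔NpT round trip rather than as an absolute
match to the input equation of state at `r_c = 4σ`.

## 7. Square-gradient bulk neutrality

The κ term shifts bulk NpT densities by an amount that scales with the
fluid's compressibility (`Δρ ≈ Δp_κ ρ β_T`).  On the stiff ambient water-like
liquid (associating backend, 300 K, 28 MPa, κ = 0.4 K nm⁸) the measured shift
is +0.7%; on the much softer van der Waals liquid at 0.7–0.85 T_c the same κ
shifts the density by several percent.  "Bulk neutrality" is therefore a
statement about liquids far from criticality, and is asserted as such.

## 8. Defaults

| quantity | default |
| --- | --- |
| cutoff | `r_c = 4σ(T)` |
| lookup table | 4001 points, `[0, min(0.98 ρ_max, 10⁴)]` |
| displacement / ln V step | 0.3 nm / 0.02, adapted to 35% during equilibration |
| sampling stride | every 10 cycles |
| test-area ξ / test-volume ζ | 5×10⁻⁴ / 10⁻⁴ |
| block averaging | 20 blocks |
| slab lateral box | `L_x = L_y = 3 r_c`, overall density ≈ critical |
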