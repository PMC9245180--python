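# Methods

## Continuum model

The model describes a 1:1 (more generally ν:ν) symmetric electrolyte in an
uncharged cylindrical nanopore (radius *R*, length *L*) whose membrane is
decorated by a coaxial annular cavity (width *w*, depth *d* = *L* − *h*,
wall thickness *s*, solid permittivity ε_S). It is a quasi-1D reduction of
the Poisson–Nernst–Planck / Navier–Stokes description under the standard
assumptions: dilute solution, equal and homogeneous ion mobilities μ, thin
Debye layers (λ_D ≪ *R*), creeping flow, and superposition of fixed-charge
and induced-charge contributions.

**Lateral capacitance.** At steady state the dead-end cavity carries no
current, so it is isopotential with the reservoir it opens toward, while the
lumen potential falls linearly between the reservoirs (uniform axial
conductivity). The annular solid wall between lumen and cavity acts as a
distributed capacitor with per-unit-length capacitance
c′ = 2π ε₀ ε_S / ln(1 + s/R) (the exact coaxial-cylinder form; it reduces to
the planar 2πR ε₀ ε_S/s for s ≪ R). Integrating c′ against the local
cavity–lumen potential difference ΔV·z/L over the cavity depth gives

    C_s = π ε₀ ε_S d² / (L ln(1 + s/R)),

the d²/2L factor being the quasi-1D average of the linearly growing drive.
`quasi1d.lateral_capacitance_fd` re-derives C_s without assuming the linear
profile: it solves the axial conduction equation on a grid (tridiagonal
finite differences) and accumulates the induced charge cell by cell; the
closed form agrees with it to discretisation error, far inside the 2%
envelope asserted in the tests. C_s vanishes as d → 0 (the geometry becomes
mirror-symmetric), grows with d, shrinks with s, and — at fixed residual
solid h — grows with L, because d = L − h grows faster than the 1/L
dilution of the drive.

**Induced charge and selectivity.** q_N = −C_s ΔV (cavity facing the biased
reservoir; the `cavity_side` flag mirrors the geometry and flips every odd
quantity coherently). Electrophoretic fluxes μc_±E make the flux imbalance
proportional to the net IDL density, so the selectivity is implemented as
ΔJ = μ⟨ρ_el⟩|E_z|/(νe). The magnitude of the driving field (rather than its
signed value) enters deliberately: the selectivity must invert with the
voltage while its magnitude grows quadratically, and composing the odd q_N
with a signed field would instead produce an even ΔJ. The convective (EOF)
contribution to ion transport is excluded by construction — measured
selectivities from trajectories are therefore expected to exceed the model
value slightly, since the EOF advects the majority carrier.

**Electroosmosis.** For λ_D ≪ R the pore charge sits in a wall layer whose
planar-capacitor relation q_N = 2πRL·ε₀ε_Lζ_w/λ_D defines the induced
electrokinetic potential ζ_w; the Helmholtz–Smoluchowski plug velocity then
gives v_eo = q_N λ_D ΔV/(2πRL²η) ∝ −C_s ΔV², even in ΔV and directed toward
the cavity opening for either polarity. The fixed-charge analogue uses
ζ_w = σ_w λ_D/(ε₀ε_L), giving v_eo,FC = −σ_w λ_D ΔV/(ηL). Equating the two
magnitudes yields the threshold ΔV* = 2πRL|σ_w|/C_s, in which λ_D and ε_L
cancel — ΔV* is a purely geometric quantity times σ_w. With L/h = 3 and
s/R = 0.5 it reduces to ΔV* = 4.5·σ_w·R·ln(1.5)/(ε₀ε_S), independent of the
absolute pore size scale except through R. σ_w(pH) surface-chemistry models
are accepted as user-supplied callables (`SurfaceChargeSpec.from_ph_model`);
no literature fit coefficients are embedded.

**Validity guards.** `eof_flow` warns (ThinLayerWarning) for λ_D/R > 0.2 and
raises (DebyeOverlapError) for λ_D ≥ R. The 0.2 soft threshold is a package
choice; note that the reference 2 M model fluid in a 10 Å pore sits exactly
at the warning edge, so thin-layer predictions there are extrapolations that
nonetheless track simulation data well.

**Units.** Everything internal is Å / ns / e / V / Da / K (ε₀ =
5.5263×10⁻³ e/(V·Å), k_B = 8.6173×10⁻⁵ eV/K). Users supply concentration in
mol/L, viscosity in mPa·s and surface charge in mC/m²; `units.py` holds the
conversions, and a test evaluates the full model independently in SI and
checks agreement to six significant digits.

## Trajectory analysis

- **Currents.** I = Σᵢ qᵢΔzᵢ/(Δt·L_z) per frame pair, with minimum-image Δz
  along the periodic axis. The estimator assumes no particle moves farther
  than L_z/2 between frames; wrapped steps beyond 0.4·L_z trigger a warning.
  Species-resolved currents restrict the sum; additivity and the telescoping
  identity (interval sums equal the endpoint estimate for noiseless drift)
  are exact and tested.
- **Flow rate.** The same estimator with masses gives a mass flow, divided
  by the bulk mass density n₀·M (n₀ from the stated bulk concentration, M
  the mean selected particle mass unless given explicitly) to yield Q_eo.
- **Block averaging.** Contiguous blocks (default 10 ns) after a transient
  discard (default 30 ns); the standard error is std(block means)/√N. At
  least two complete blocks are required.
- **Velocities and fields.** Central differences over 2Δt (exact through
  quadratic motion), binned on an (r, z) grid about the pore axis with true
  annular volumes π(r_out²−r_in²)Δz and default 1 Å bins. Empty density
  bins are 0 (a measured absence); empty velocity bins are NaN/masked, since
  zero-filling would bias profile averages. The pore-charge integral uses
  the full cylinder r < R, |z| < L/2; the 2λ_D axial margin of `RegionSpec`
  is intended for velocity-profile extraction only.
- **Diffusion/mobility.** MSD on unwrapped coordinates with non-overlapping
  time origins by default (overlapping origins smooth the curve but correlate
  the residuals); D = slope/6, with an R²/curvature diagnostic that flags
  ballistic or otherwise non-diffusive fits. μ = νeD/k_BT.

## Synthetic data

The generator produces non-interacting overdamped-Langevin walkers
(x ← x + vΔt + √(2DΔt)·N(0,1), periodic wrap) because analysis-operation
correctness requires closed-form ground truth, not physical realism. Default
frame interval 0.05 ns. When a membrane is attached, moves ending in the
solid are reflected off the nearest slab face and rejected (position kept)
if the reflection fails — an artifact choice that only needs to keep walkers
out of the solid. The default lateral box maps the hexagonal apothem rule
a_h = 2.1(R+s+w) to a square cell of equal area, with L_z = 2a_h + L.

Three fixtures: (i) **drift** trajectories with per-species planted drift —
the planted current n·q·v_z/L_z and mass flow are exact closed forms (valid
only without the membrane, which obstructs drift); (ii) **IDL**
configurations with unit-charge carriers placed in the lumen with
wall-peaked radial density ∝ exp(−(R−r)/λ_D) plus the mirror-signed excess
in the cavity and neutral background pairs for counting noise — the planted
lumen charge is exact in every frame and flips with the voltage-polarity
sign; (iii) **Poiseuille-like** profiles with radius-dependent axial drift
(parabolic or plug), drift re-evaluated at the current radius each step.

What the synthetic data does *not* emulate: ion–ion and ion–solvent
interactions, electrostatic self-consistency between the planted IDL and any
field, hydrodynamic coupling, finite-size and entrance effects. Passing the
round-trip tests therefore certifies the *estimators* (binning, unit
conversions, error bars, minimum-image bookkeeping), not the physics of any
particular simulated electrolyte.

## Numerical and statistical choices

- Recovery tests run 20 independent seeds with modest sizes (≈ 360 walkers ×
  700 frames for transport, 12 replicate configurations for the IDL charge)
  and require each-seed agreement within 3 standard errors for at least 19
  of 20 seeds plus pooled agreement within 3 pooled standard errors; a
  strict all-seeds-at-3σ rule would fail a correct estimator several percent
  of the time.
- Diffusion recovery fits short lags (≤ 0.5 ns) so that the v²t² drift
  contribution to the MSD stays below a percent of 6Dt.
- The quasi-1D capacitance cross-check uses 2000 axial cells; midpoint
  integration makes the discretisation error effectively nil for the linear
  potential profile, so the 2% tolerance is dominated by nothing — it simply
  pins the two routes together.
- Degenerate inputs: d = 0 gives C_s = 0 and ΔV* = +inf (no cavity, induced
  mechanism never catches up); σ_w = 0 gives ΔV* = 0; empty species lists
  generate valid empty trajectories whose analyses return zeros.

## Known limitations

- The thin-layer closure overestimates EOF for short pores and λ_D ≳ R/5;
  no Debye-overlap modelling is attempted.
- ΔJ omits convection, so it is a lower bound relative to full simulations.
- The superposition behind ΔV* (fixed + induced contributions adding
  linearly) is heuristic; treat ΔV* as a crossover scale, not a sharp
  transition.
- The CLI's `analyze` assumes NVT-style frames (constant box, fixed particle
  set); trajectories with changing topology are rejected.
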