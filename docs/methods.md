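# Methods

## Model and assumptions

Both models treat slow periodic flow in rigid geometry, so the momentum
balance reduces to a linear resistive network: Δp = Rq per element,
Kirchhoff mass conservation per node, and grounded boundary nodes at the
zero far-field pressure reference (fluid freely enters/leaves the modeled
region axially along the PVS and radially/laterally through the tissue
boundaries; no background pressure gradient is imposed). The drivers are
volumetric sources equal to the fluid volume rate displaced by the moving
vessel wall.

Assumptions, each checked by a reported diagnostic:

- **Quasi-steady profiles.** The Womersley number
  α = 2(R_o − R_i)√(2πfρ/μ) ≈ 0.24 at baseline, so the oscillatory flow in
  the annulus is well approximated by the steady profile of the
  instantaneous pressure gradient.
- **Uniform wall motion.** The pulse wavelength c/f = 0.2 m exceeds the
  300 μm segment by a factor ~667, so the wall moves in phase along the
  segment and lubrication theory applies (axial gradients dominate).
- **Linearized sources.** The exact displacement rate
  dV/dt = 2πl·r_i·ṙ_i differs from the sinusoidal linearization by at most
  b/R_i (2.5% at baseline); the solver uses the linearized form, and the
  exact form is retained for the error-bound test.
- **Constant resistance.** Within a cycle the annulus resistance is
  evaluated at the mean radius R_i. At baseline the excursion changes it by
  < 5%; sweeps into narrow-gap territory reduce the amplitude by the
  bracketing-root-search rule (below) to keep that bound.
- **Rigid porous tissue.** Parenchyma deformation, viscoelasticity and any
  time-varying conductivity are outside scope, as are mechanisms that could
  produce net flow (CSF pressure transients, capillary filtration).

## Network layouts

**One-vessel** (7 resistors, 3 sources): axial PVS chain
R1(50 μm)–R2(100)–R3(100)–R4(50) with both ends grounded; interior nodes
n1–n3 each carry a source (IA1–IA3, 100 μm of vessel, g = 4π²) and a radial
shell element (R5–R7, 10 → 300 μm, h = 100 μm) to ground.

**Two-vessel** (25 resistors, 6 sources): the planar region between an
arteriole and a vein 200 μm apart. Half-annulus PVS chains (resistance
doubled) run down the two sides; a Darcy-slab grid with node columns at 50
and 150 μm from the arterial PVS fills the tissue between; top and bottom
tissue boundaries are grounded through 50 μm slabs. Resistors are numbered
in row-major reading order of the planar figure, which lands the 100 μm
lengths exactly on R6, R8, R9, R10, R11, R13, R15, R16, R17, R18 and R20
(all others 50 μm) — the canonical assignment. Arterial sources use
g = 2π²; venous sources additionally carry amplitude ξ·b and phase θ. The
full layout is exported to `topology.yaml` so alternative wirings can be
diffed without reading code.

### Velocity conventions

Velocities are superficial (volumetric flow over total cross-section):

- full annulus: q / π(R_o² − R_i²);
- radial shell: q / 2πrh at a caller-chosen radius (default: the PVS outer
  radius, i.e. "adjacent to the PVS"; the standard far evaluation point is
  50 μm beyond it);
- slab: q / (h·d);
- **half-annulus elements divide by the full annular area.** The modeled
  half-PVS carries half the total axial flow of the (symmetric) full
  annulus at doubled resistance, so flow-per-total-area is the physically
  comparable velocity of the whole PVS. This convention reproduces the
  expected halving of the two-vessel arterial PVS peak velocity relative to
  the one-vessel model at equal peak pressure; dividing by the half-area
  would instead return the one-vessel velocity unchanged, which is
  inconsistent with the two-vessel model's published behaviour.

## Parameters

Defaults (SI internally; accepted config units include μm, nm, Hz, mPa·s,
mmHg, μm²/s, μm³·s/kg):

| symbol | meaning | baseline | swept range |
|---|---|---|---|
| R_i | PVS inner (vessel) radius | 10 μm | 1–29 μm |
| R_o | PVS outer radius | 30 μm | 2–30 μm |
| L_PVS | vessel segment length | 300 μm | — |
| L_PCY | inter-vessel distance | 200 μm | — |
| b | pulse amplitude | 0.25 μm | 0–0.37 μm |
| f | pulse frequency | 5 Hz | — |
| — | pulse wave speed | 1 m/s | — |
| K (K_PCY) | parenchyma hydraulic conductivity | 5.63×10⁻¹² m²/(Pa·s) | 10²–10¹¹ μm³·s/kg |
| K_PVS | porous-PVS conductivity | 5.63×10⁻¹² | 10²–10¹¹ μm³·s/kg |
| μ, ρ | ISF viscosity, density | 0.9 mPa·s, 993.2 kg/m³ | — |
| ϕ, η | tissue porosity, pore size | 0.2, 60 nm | — |
| D* | solute diffusivity | 100 μm²/s | 10–10³ μm²/s |
| l, h, d | element length / height / depth | 50;100, 100, 200 μm | — |
| R_i^PCY, R_o^PCY | shell radii | 10, 300 μm | — |
| ξ | venous:arterial pulsatility ratio | 0.80 | 0–1 |
| θ | venous phase delay | 0 | 0–2π |

Notes on contested/ambiguous values, resolved here once:

- The parenchyma shell inner radius is 10 μm (the vessel wall) even though
  the PVS outer radius is 30 μm; the printed parameter table value is used
  as-is. The resistance is logarithmic in the ratio, so the alternative
  (30 μm) choice would lower shell resistance by ~32% and raise tissue
  velocities accordingly — without changing any regime conclusion.
- Pulsatility is evaluated by adaptive quadrature of Π = 2∫₀ᵀ|r_i − R_i|dt
  with T defaulting to one period, giving 4b/(πf). The often-quoted closed
  form b/(πf) differs by a constant factor; since only the venous:arterial
  ratio ξ enters the model, the discrepancy has no downstream effect, and
  the ratio is implemented directly as b_ven = ξ·b_art.
- The wall-motion phase convention r_i = R_i − b·cos(2πft − θ) makes t = 0
  the minimum-radius instant and gives zero source rate at t = 0.

## Numerics

- **Time discretization.** 256 samples over one period (plus the endpoint
  sample, so full-period trapezoidal integrals vanish identically for
  sinusoids). Peaks change by < 0.1% on doubling; the suite solves most
  property checks at 64 samples, where peak-location error on a sinusoid is
  still < 0.2%.
- **Linear solves.** The reduced conductance matrix over non-grounded nodes
  is symmetric positive definite whenever every node reaches ground (a BFS
  check with a named-node error otherwise); one Cholesky factorization is
  reused across all time samples. Largest system: 12 unknowns.
- **Conservation.** Per-node Kirchhoff residual is reported relative to the
  peak source rate; baseline values are ~10⁻¹⁵ (machine precision).
- **Amplitude-tolerance rule.** The largest pulse amplitude keeping the
  free-fluid annulus resistance within tolerance (default 5%) of its
  mean-radius value is found by Brent root search on the maximum relative
  deviation over the excursion endpoints (the deviation is monotone in
  |r_i − R_i|, worst on the narrow-gap side); f(0) = −tol provides the
  lower bracket. For a 1 μm gap at R_o = 30 μm it returns 16.22 nm,
  within 1% of the thin-film cubic-law estimate gap·(1 − 1.05^(−1/3)).
- **Sweep grids.** Conductivities log-spaced over the simulated range,
  everything else linear. Invalid grid points (e.g. R_i ≥ R_o) are skipped,
  logged and recorded in the table's `attrs["skipped"]`.
- **Phase sweep sampling.** Signed velocities are read a quarter period
  into the arterial waveform (its maximum); `n_samples` must be divisible
  by 4 so T/4 lies on the grid.
- **Determinism.** There is no randomness anywhere; reports round floats to
  9 significant digits and sort keys so identical runs are byte-identical.

## What the baseline runs show

(Computed by the test suite and `scripts/acceptance.py`; nothing here is
asserted that those do not recompute.) One-vessel baseline: peak PVS
velocity 29.4 μm/s at the chain ends, peak pressure 64.9 mPa at the center
node, tissue velocity 3.58 nm/s adjacent to the PVS falling as 1/r to
1.34 nm/s at 50 μm. Two-vessel baseline: arterial PVS peak 14.7 μm/s
(half the one-vessel value), peak pressure 64.9 mPa, tissue velocities
≤ 2.7 nm/s in the 50–150 μm band in both orientations, arteriovenous
pressure gradient ~5×10⁻⁴ mmHg/mm. PVS Peclet numbers reach ~880 at
D* = 10 μm²/s while parenchyma Peclet numbers stay below 0.04
(inter-vessel convention, pore-size convention for the smallest D*):
oscillatory dispersion can matter in the PVS, but tissue transport is
diffusive.

## Limitations

- The network is a coarse discretization: one radial element per source
  node in the one-vessel model, a 3×3-ish grid in the two-vessel model.
  Velocities between nodes are only as local as the element areas used to
  convert them.
- No PVS branching or tapering, no deformable tissue, no aquaporin/endfoot
  modeling beyond its lumped effect on K_PCY, no net-flow mechanisms, and
  no quantitative dispersion coefficient — the Peclet numbers bound the
  convective contribution, nothing more.
- The two-vessel wiring is a reconstruction constrained by the element
  count, the published length assignment and the baseline outputs; the
  serialized topology file is the authoritative statement of what was
  solved.
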