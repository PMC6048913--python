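# pvsnet

Lumped-parameter hydraulic network models of the pulsatile fluid motion that
blood-vessel wall pulsations drive in cortical **perivascular spaces (PVS)**
and the surrounding brain **parenchyma**, with transport-regime (Peclet
number) diagnostics and parameter sweeps.

The PVS is the annular extracellular channel around penetrating arterioles
and veins; whether the cardiac pulse drives convective solute transport
through it and into brain tissue is a central question for glymphatic-style
clearance theories. `pvsnet` answers the fluid-mechanics half of that
question with a deliberately minimal model: resistor networks driven by
volumetric sources that represent the fluid displaced by a sinusoidally
moving vessel wall. It is aimed at researchers in brain biotransport who
want desk-scale, fully inspectable estimates of perivascular and
interstitial flow, for example to sanity-check CFD models.

## Model

Fluid motion obeys the hydraulic Ohm's law, Δp = Rq. Element resistances:

- free-fluid PVS annulus (steady Poiseuille):
  `R = 8μl / (π R_o⁴ [1 − E⁴ + (E² − 1)²/ln E])`, `E = R_i/R_o`
- porous PVS annulus (Darcy): `R = l / (π (R_o² − R_i²) K_PVS)`
- radial parenchyma shell (Darcy): `R = ln(R_o^PCY/R_i^PCY) / (2π h K_PCY)`
- rectangular parenchyma slab (Darcy): `R = l / (K_PCY h d)`

The vessel wall moves as `r_i(t) = R_i − b·cos(2πft − θ)`, displacing fluid
at the rate `q ≈ g·l·f·b·R_i·sin(2πft − θ)` with geometry factor `g = 4π²`
(full annulus, one-vessel model) or `2π²` (half annulus, two-vessel model).
These sources are the only flow drivers — no pressure gradient is imposed.
The quasi-steady, constant-resistance treatment is justified by the small
Womersley number (α ≈ 0.24 at baseline) and by the pulse wavelength
(c/f = 20 cm) far exceeding the 300 μm modeled segment.

Two layouts are built in: a **one-vessel** model (an arteriole's PVS as a
four-resistor axial chain, three pulsatile sources, three radial shells into
tissue; 7 resistors) and a **two-vessel** model (arteriole and vein 200 μm
apart, half-annulus PVS chains bridged by a planar Darcy grid; 25
resistors, arterial plus venous sources with pulsatility ratio ξ and phase
delay θ). Transport regime is assessed with Peclet numbers
`Pe = L_PVS·v/D*` (PVS) and `Pe = Lv/(ϕD*)` (parenchyma, with L the
inter-vessel distance or the tissue pore size).

## Worked example

```python
from pvsnet import (ModelParameters, build_one_vessel, build_two_vessel,
                    ONE_VESSEL_PVS, TWO_VESSEL_ARTERIAL_PVS)

one = build_one_vessel(ModelParameters.baseline()).solve_period(256)
print(f"PVS peak velocity  {one.peak_velocity(ONE_VESSEL_PVS)*1e6:.1f} um/s")
print(f"peak pressure      {one.peak_pressure()*1e3:.1f} mPa")
print(f"tissue velocity    {one.peak_velocity(['R6'], radius=30e-6)*1e9:.2f} nm/s")

two = build_two_vessel(ModelParameters.baseline("two_vessel")).solve_period(256)
print(f"arterial PVS peak  {two.peak_velocity(TWO_VESSEL_ARTERIAL_PVS)*1e6:.1f} um/s")
```

prints

```
PVS peak velocity  29.4 um/s
peak pressure      64.9 mPa
tissue velocity    3.58 nm/s
arterial PVS peak  14.7 um/s
```

i.e. vessel pulsation moves perivascular fluid at tens of μm/s (oscillatory,
with zero net volume over a cycle — convection cannot be the whole story,
but dispersion can be significant, Pe up to ~10³), while tissue velocities
stay at nm/s (Pe ≲ 10⁻¹: solute transport in parenchyma is
diffusion-dominated).

The same runs from the shell:

```sh
pvsnet run --model one_vessel --out out/        # summary.json, timeseries.csv, topology.yaml
pvsnet sweep amplitude --out out/               # sweep_amplitude.csv
pvsnet check                                    # baseline self-check as JSON
```

Parameters come from a YAML file (`--config`) or per-key overrides
(`--set 'b=0.1 um'`); keys are the conventional symbols (`R_i`, `R_o`, `b`,
`f`, `K`, `xi`, `theta`, ...), values either SI numbers or `"value unit"`
strings (μm, nm, Hz, mPa·s, μm³·s/kg, ...).

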