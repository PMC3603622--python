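# coroflow

Coupled heart–coronary–systemic hemodynamics in Python: a single-fiber
left-ventricle contraction model drives a one-dimensional wave-propagation
model of the aorta, its major branches and a coronary tree, closed by
three-element windkessel terminals and intramyocardial-pressure-loaded
microvascular beds. A semi-empirical stenosis element and a
microstructure-based coronary wall law allow simulation of epicardial
stenoses (with fractional flow reserve, FFR) and of left-ventricular
hypertrophy with aortic valve stenosis (LVH-AVS).

The package is aimed at cardiovascular modellers who need a transparent,
fully deterministic forward model of coronary pressure and flow — for
example to study how epicardial and microvascular disease combine in
clinically used indices such as FFR, or to prototype boundary conditions
for 3D models.

## Model

**Ventricle.** The LV is a thick-walled sphere of incompressible myocardium
described by one representative fiber. Cavity pressure follows from the wall
stress balance

p_lv = ⅓ (σ_f − 2 σ̄_r) ln(1 + V_w/V_lv),

with fiber stress σ_f = σ_p(l_s) + σ_a(l_s, v_s, t_a); the active part is
σ_a = c·g₁(l_s)·g₂(t_a)·g₃(v_s) (length, activation-time and Hill-type
force–velocity factors). The mid-wall shell also provides the
intramyocardial pressure p_im = σ̄_r + ((r_o−r̄)/(r_o−r_i))·p_lv that
compresses the coronary microvessels — the cause of systolic impediment of
coronary inflow.

**Vessels.** Each 1D segment obeys ∂A/∂t + ∂Q/∂z = 0 and a momentum balance
closed by an approximate velocity profile (inertial core + Stokes layer,
parametrised by the Womersley number α = a√(2πρf/η)); at low α the scheme
reduces exactly to Poiseuille flow. Coronary walls use a Langewouters-type
compliance C(p) = C₀ + C₁/(1+((p−p_m)/p_w)²) with geometry-dependent
coefficients pre-fitted against a two-fiber (helical collagen) thick-wall
model, which ships as an independent oracle; systemic walls are linear
elastic (E = 0.4 MPa). Stenoses are lumped elements with viscous, turbulent
(∝|Q|Q), inertial and mean-flow terms after Young–Tsai/Bessems. Coronary
radii follow Murray's law down to fourteen 1 mm terminal vessels, each
ending in a four-resistor/three-capacitor microvascular ladder
(R split 7:9:9:2) referenced to p_im.

Everything is integrated fully coupled with backward Euler and one sparse
direct solve per time step, run until periodic.

## Worked example

```python
from coroflow import CoronaryCirculationModel

model = CoronaryCirculationModel.from_scenario("healthy")
res = model.simulate()          # ~15 s: 8 cycles to periodicity
print(res.summary())
```

```
stroke_volume_ml              74.132305
cardiac_output_l_min           5.082473
mean_aortic_pressure_mmhg     99.741959
pulse_pressure_mmhg           51.845234
systolic_pressure_mmhg       131.232098
diastolic_pressure_mmhg       79.386864
lmca_flow_ratio                3.174209
rca_flow_ratio                 1.198028
cycles                                8
converged                          True
```

A stroke volume of 74 mL at 99.7/51.8 mmHg mean/pulse aortic pressure is a
normal resting hemodynamic state; the left main coronary flow is
diastolic-dominant (max-diastolic/max-systolic ratio 3.2) with the typical
early-systolic flow reversal, while the right coronary artery — loaded by
the weaker right-ventricular intramyocardial pressure — is nearly balanced
(ratio 1.2).

A stenosis under hyperaemia:

```python
res = CoronaryCirculationModel.from_scenario("stenosis-severe").simulate()
print(round(res.ffr(), 3))      # 0.626 across the 70%, 7.48 mm LAD lesion
```

An FFR of 0.63 is well below the 0.80 ischemia threshold, i.e. a
hemodynamically significant lesion; the mild (50%, 2.65 mm) lesion gives
0.943. Scenario names: `healthy`, `stenosis-mild`, `stenosis-severe`,
`lvh-pre`, `lvh-post`. The same runs are available from the shell:

```
coroflow run stenosis-severe --summary-out ffr.json
coroflow describe            # network table
coroflow wall-oracle         # two-fiber pressure-radius-compliance table
```

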