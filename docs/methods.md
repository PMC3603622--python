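# Methods

This note documents the model equations as implemented, the parameter
choices that matter, the numerical scheme, and the places where the design
was genuinely open — together with what the shipped tests do and do not
establish.

## Heart

The left ventricle is a thick-walled sphere of incompressible myocardium
with a single representative myofiber. The kinematics tie sarcomere stretch
to cavity volume through the shell that encloses the cavity plus one third
of the wall volume:

- λ_f = ((V_lv + V_w/3)/(V_lv0 + V_w/3))^(1/3), λ_r = λ_f⁻², l_s = λ_f·l_s0.
- p_lv = ⅓ (σ_f − 2σ̄_r) ln(1 + V_w/V_lv).
- σ_f = σ_p + σ_a with σ_a = c·g₁(l_s)·g₂(t_a)·g₃(v_s); g₁ and g₂ are
  squared-tanh shapes, g₃ = (v_s0 − v_s)/(v_s0 + c_v v_s) is the Hill-type
  force–velocity relation with v_s = −dl_s/dt. Passive fiber/radial
  stresses are exponential and engage on opposite sides of l_s0.
- p_im = σ̄_r + ((r_o − r̄)/(r_o − r_i))·p_lv at the same representative
  shell; the weight is ≈0.55–0.59 over the working volume range.

The same shell (V_lv + V_w/3) is used for the kinematics, for σ̄_r and for
p_im, so one geometric convention runs through the whole ventricle model.

Parameter defaults (SI): V_lv0 = 60 mL, V_w = 200 mL, l_s0 = 1.9 µm,
l_sa0 = 1.5 µm, σ_a0 = 90 kPa, c_a = 2.4·10⁶ m⁻¹, t_r = t_d = 75 ms
(the printed activation table lists a single "t_a" rise row, which we map to
the rise constant of the activation function since that is the only constant
the equation needs and decay is listed separately), t_max = 0.4 s,
v_s0 = 10 µm/s, c_v = 1, σ_p0 = 0.9 kPa, c_p = 12, σ_r0 = 0.2 kPa, c_r = 9.
The hypertrophic (pre-AVR) variant sets V_w = 250 mL and c = 1.4.

**Heart period.** The sources do not print a heart rate. We fix T = 0.875 s,
the period at which a 70 mL stroke volume yields a 4.8 L/min cardiac output;
the Womersley closure uses f = 1/T. T is a config parameter.

## Valves

The mitral valve is an ideal diode (R_open = 4·10⁶, R_closed = 10¹²
Pa·s/m³) fed from a constant pulmonary venous pressure of 1200 Pa (no
atrium). The aortic valve is a resistance–inertance element,
Δp = L_av dQ/dt + R_av Q with L_av = ρ l_av/A_av ≈ 1.55·10⁴ Pa·s²/m³; it
opens on a positive ventriculo-aortic gradient and closes when its flow
turns negative. Valve state is switched once per time step from the previous
solution, keeping each implicit solve linear; at dt = 0.5 ms the one-step
lag is negligible. The closed state keeps the same equation with the large
resistance, so a physical leak of order Δp/10¹² remains.

## 1D vessels

Mass: ∂A/∂t + ∂Q/∂z = 0 with ∂A/∂t = C(p)·∂p/∂t through the wall law
(distributed side-leakage ψ and body force f_z are zero). Momentum uses the
approximate-velocity-profile closure (inertial core fraction
ζ_c = (max[0, 1 − 2/α])², convective factor δ(ζ_c)); substituting the wall
shear closure merges the two pressure-gradient terms into the effective
coefficient (A/ρ)(1 + ζ_c)/2 and a friction term 4πη/(ρ(1−ζ_c)A)·Q. For
steady flow at α ≤ 2 this is exactly Poiseuille's law (verified against the
analytic gradient to < 1% in the tests). α is fixed per segment from its
physiological mean radius and the heart rate. The printed closure forms
(including δ(0) = 2 rather than the parabolic 4/3) are kept as printed.

Blood: ρ = 1050 kg/m³, η = 4 mPa·s.

## Wall laws

*Systemic*: thin-tube linear elasticity, C = 2π(1−µ²)a_p³/(h_p E) with
E = 0.4 MPa, µ = 0.5, pressure-independent, anchored at A(13.3 kPa) = πa_p².

*Coronary*: Langewouters-type Lorentzian compliance
C(p) = C₀ + C₁/(1 + ((p−p_m)/p_w)²), with all four parameters polynomial in
the thickness ratio κ = h_p/a_p (κ = 0.1 throughout the coronary tree) and
the amplitudes proportional to lumen area. A(p) is the closed-form integral
(arctan) anchored at 13.3 kPa.

**Unit resolution of the amplitude rows.** The printed coefficient table is
dimensionally ambiguous (the amplitude rows cannot both be read in the same
unit once the area prefactor is applied). We implemented the underlying
two-fiber thick-wall model — neo-Hookean matrix (G = 19.3 kPa) with two
helical collagen families (k₁ = 2.01 kPa, k₂ = 5.10, β₀ = 34.6°), opening
angle and axial stretch calibrated so that (i) circumferential stress is
uniform across the wall and (ii) the deformed fiber angle equals 36.4° at
13.3 kPa — and used it as the arbiter. The p_m and p_w polynomials agree
well with an unconstrained refit of the oracle curve (peak ≈ 1.8–2.1 kPa,
width ≈ 1.8 kPa). The adopted amplitude reading,
C₁,₁ = 1.09·10⁻⁹ m²/Pa and C₀,₁ = 284·10⁻¹³ m²/Pa with an A_p/(π mm²)
scaling, tracks the oracle within 15% over 2–13.3 kPa and reproduces
coronary pulse-wave speeds near 10 m/s; on the stiff tail (13.3–20 kPa) the
deviation grows to ~50% and no power-of-ten reading of the printed values
removes it. Quantities that depend on the low-pressure compliance contrast
between the Langewouters and linear laws (notably the wall-shear-stress
difference distal to a severe stenosis) inherit this uncertainty.

The comparison wall law for the wall-model study is linear with E = 1.5 MPa
on the coronary tree only.

## Stenosis element

An axisymmetric narrowing of length L_s and throat radius a_s (uniform
cylinder at the stated % diameter reduction by default; arbitrary profiles
supported) is replaced by a rigid lumped element:

Δp = K_v R_st Q + (ρK_t/2A₀²)(A₀/A_s − 1)²|Q|Q + K_u L_u dQ/dt + K_c R_st Q̄,

K_v = 1 + 0.053 (A_s/A₀) α, K_t = 0.95, K_u = 1.2, K_c = 0.0018 α², with
R_st and L_u the Poiseuille-resistance and inertance integrals over the
throat profile. Q̄ is the running mean over the most recent completed cycle.
In the network the drop is distributed linearly over L_s (differential
form), the |Q|Q term is linearised with the previous |Q|, and the element
carries no compliance. The mild (50%, 2.65 mm) and severe (70%, 7.48 mm)
lesions replace the mid portion of the middle LAD segment (radius 1.59 mm).
Note that K_v and K_c do not reduce to the plain 1D element as A_s → A₀
(at α ≈ 2 they add ~12% viscous drop), so the embedding-consistency check is
meaningful only at small α.

## Terminals

*Systemic* (11 outlets): three-element windkessel — wave impedance Z in
series with R_w ∥ C_w draining to a constant venous 700 Pa. Z, R_w, C_w per
outlet are taken from the printed per-vessel table (whose values all satisfy
R_w·C_w = 1.50 s; the accompanying text states τ = 2 s — an internal
inconsistency of the source; the table wins here).

*Coronary* (14 beds): serial ladder R_art–C_art–R_myo1–C_myo–R_myo2–C_ven–
R_ven with R_art:R_myo1:R_myo2:R_ven = 7:9:9:2 of R_t, and all three
capacitors referenced to the intramyocardial pressure. R_t per bed is
Ohm's law at 100 mmHg mean pressure over the venous level and 20 mL/min per
terminal (3.79·10¹⁰ Pa·s/m³). RCA beds see
p_ext = (0.4 + 0.6·0.2)·p_im = 0.52·p_im (the RCA supplies LV and RV in a
0.4 ratio and RV intramyocardial pressure is 0.2 of the LV's).

**Capacitance scale.** The printed compartment compliances
(0.2/0.53/0.65 mm³/Pa) are organ-level measurements; we distribute them
evenly over the 14 parallel beds. Used per bed as printed they give
arterial-compartment time constants above 1 s, which suppresses systolic
coronary inflow almost completely and is incompatible with the reported
diastolic/systolic flow ratios; distributed, the time constants drop below
the cardiac phase durations and the characteristic pattern (early-systolic
reversal, finite mid-systolic flow, early-diastolic surge) appears. The
simulated ratios remain somewhat above the reported ones (see Limitations).

**Hyperaemia** divides the two myocardial resistances by 5 (config
parameter). Dividing all four bed resistances by 5 — the literal reading of
"microvascular resistances" — cannot reproduce the reported FFR pair
(closed-form bed+stenosis balance gives ≈0.81/0.36 vs the reported
0.96/0.61), while the myocardial-only division lands on ≈0.95/0.61; a
literal five-fold flow increase is in fact impossible while the arterial and
venous fractions are retained, since they alone exceed R_t/5.

## Network

Aorta and major branches: 22 segments with printed lengths, radii, wall
thicknesses. Coronary tree: left main (5 mm) off the aortic root 5 mm
distal to the valve, splitting into LAD (7.5 cm) and LCx (6 cm); the RCA
duplicates the LAD geometry. Side branches (1 cm long, radius 1 mm — the
side-branch length is not printed; 1 cm is our choice, configurable) leave
the main stems at 1.5 cm intervals; the stem beyond the last branch point is
itself a 1 mm terminal. Murray's law (cube-sum) sizes the inter-branch stem
segments from the leaves upward: LAD stem radii 1.71/1.59/1.44/1.26 mm,
LMCA 2.08 mm. Every coronary wall thickness is 10% of the local radius.

## Numerics

- Staggered 1D grid: pressures on nodes, flows on elements of nominally
  2.5 mm; node mass balances lump the compliance of adjacent half-elements;
  junctions share nodes (pressure continuity + flow conservation).
- One backward-Euler step solves all unknowns (heart volume and pressure,
  valve flows, nodal pressures, element flows, lumped pressures — 938 for
  the full network) in a single sparse LU factorisation. Wall compliances
  and areas are Picard-lagged; convective and axial-diffusion terms are
  explicit (peak Courant number ~0.4 at the default step).
- The ventricular pressure is linearised in (V_lv, v_s) with numerical
  partials about the previous state; the force–velocity slope then acts as
  an implicit internal resistance, which is what makes the ejection phase
  stiffly stable. The bed capacitors use a linearised p_im reference that is
  stored and re-used so the capacitor charge telescopes exactly over a
  cycle (no spurious pumping).
- dt = 0.5 ms by default. Halving it changes cycle means by ≤0.01%
  (pressures) and ≤0.4% (pulse/ratios). Valve transitions are resolved.
- Periodicity: cycles are integrated until stroke volume, mean aortic
  pressure and mean coronary inflow all change < 0.1% between cycles
  (typically 7–9 cycles from the cascade-initialised state; ~15 s per run
  on one CPU).
- No randomness anywhere: identical configs give bit-identical results.

Degenerate inputs: non-positive volumes/areas raise typed errors; the
force–velocity pole is clamped at 0.99 of its location (log entry); a
singular or non-finite solve aborts with the offending unknowns named.

## What the tests show

Unit tests pin every closed-form relation to independently computed values;
property tests cover incompressibility, monotonicity, conservation and
determinism. The solver is checked against three independent oracles: the
analytic Poiseuille gradient (steady, < 1%), a continuous-time solve_ivp
integration of a reduced network (first-order convergence of the implicit
scheme), and the two-fiber wall model. The acceptance suite re-runs all
scenarios end-to-end. These are all checks of the model's internal
consistency and of agreement with the published simulation outputs — not a
validation against measured patient data, which the package does not ship.

## Limitations

- Simulated systolic coronary inflow is lower than reported: the LMCA
  diastolic/systolic ratio comes out ≈3.2 (reported 2.1) and the RCA ratio
  ≈1.2 (reported simulation 0.9 — though 1.2 is the reported *measured*
  value). The ratio varies monotonically with the microvascular capacitance
  scale between ≈7.5 (per-bed printed values) and ≈1.2 (zero capacitance);
  no defensible reading of the printed values lands on 2.1, and we do not
  fit it. The LVH systolic-extreme velocity ratio inherits this through its
  healthy-run denominator.
- The pre-AVR trans-valvular gradient is ≈60 mmHg with the printed valve
  resistance and contractility (reported ≈93 mmHg, described there as the
  result of tuning those parameters; the peak instantaneous gradient is
  ≈95 mmHg).
- The wall-law comparison reproduces the reported *pattern* (wall shear
  stress much more affected than pressure/flow/area, largest distal to the
  severe stenosis) but its magnitude (≈45% vs 17%) depends on the
  low-pressure compliance contrast, i.e. on the amplitude-unit ambiguity
  described above.
- No atrial or right-ventricular contraction, no autoregulation or
  baroreflex, axisymmetric smooth stenoses only, Newtonian blood.
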