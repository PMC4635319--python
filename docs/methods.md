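# Methods

## Model structure

The package chains four sub-models, each with a clean seam so any can be
recalibrated independently:

1. **N status** — critical dilution curve Nc = 4.8·W⁻⁰·³³ (g N per 100 g DM,
   W in t DM ha⁻¹) and NNI = Nm/Nc. Below 1 t ha⁻¹ the curve is held at its
   4.8 plateau: the allometric form is unreliable at very low standing
   biomass and the plateau is standard dilution-curve practice. NNI can also
   be supplied directly, bypassing the biomass path.
2. **Leaf N allocation** — Na = Nup·(I/I₀)^kN with Nup and kN linear in NNI
   (defaults Nup_opt = 2.17 g m⁻², a₂ = 2.15, kN_opt = 0.25, a₃ = 0). Nup is
   floored at 0; kN is clamped to [0, 1): observed allocation is always less
   than proportional to light, and an exponent ≥ 1 would invert that.
3. **Leaf gas exchange** — Farquhar biochemistry (minimum of Rubisco-,
   RuBP-regeneration- and TPU-limited rates, hard switch, limitation state
   reported) with capacities linear in Na, coupled to Leuning stomatal
   conductance and the 1.6·gs diffusion closure.
4. **Canopy integration** — 8 equal-leaf-area strata, Beer–Lambert light
   profile, per-stratum hourly solves, trapezoid daily integrals.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| Nup_opt, a₂ | 2.17, 2.15 | g N m⁻², per NNI | top-leaf N and its N-status sensitivity |
| kN_opt, a₃ | 0.25, 0 | –, per NNI | steepness of the N profile vs light |
| Na regressions | 53.03/−14.74, 90.91/−13.83, 6.72/−0.72, 0.69/−0.005 | µmol g⁻¹ s⁻¹ scale | Vcmax²⁵, Jmax²⁵, TPU²⁵, Rd²⁵ vs Na |
| Kc²⁵, Ko²⁵, Γ*²⁵, O | 404.9 µmol mol⁻¹, 278.4 mmol mol⁻¹, 42.75 µmol mol⁻¹, 210 mmol mol⁻¹ | | Rubisco kinetics (Bernacchi in-vivo set) |
| θ, α | 0.7, 0.3 | –, e⁻/photon | electron-transport light response |
| g0, a₁, D₀ | 0.02 mol m⁻² s⁻¹, 9.0, 1.5 kPa | | stomatal model |
| k | 0.8 | – | canopy extinction coefficient |
| n_strata | 8 | – | vertical discretization |

All are overridable through the YAML run configuration; unknown keys are
rejected so typos fail loudly. The stomatal defaults (a₁, D₀, g0) and the
FvCB temperature-response constants are standard-literature values, not
species-specific calibrations — they are the first thing to replace when
fitting a new dataset.

Temperature responses: plain Arrhenius for Vcmax, Rd, Kc, Ko and Γ*; peaked
Arrhenius for Jmax (Ea 43 540, Hd 152 040, ΔS 495 J mol⁻¹; optimum ≈ 29 °C);
TPU shares the Jmax response, both being regeneration-side capacities.
Night respiration equals day respiration. Leaf temperature is taken equal to
air temperature; VPD and CO₂ are uniform through the canopy.

## Numerical choices

* **Coupled solver.** The A–Ci–gs closure is a single root on Ci found by
  Brent bracketing on (Γ*+ε, Ca], tolerance 10⁻⁶ µmol mol⁻¹; the FvCB
  branch minimum is evaluated inside the residual so limitation switching
  needs no per-branch cubic algebra. When demand is non-positive even at
  Ci = Ca, gs is pinned at g0 and Ci follows the linear diffusion closure
  (rising above Ca, as respiration exports CO₂); this branch requires
  g0 > 0. Closure residuals are carried on every result and stay below
  10⁻⁷ µmol m⁻² s⁻¹ in practice.
* **Limitation ties** break in the order Rubisco < RuBP-regeneration < TPU
  (relevant exactly at Ci = Γ*, where Wc = Wj = 0).
* **A–Ci fitting.** (Vcmax²⁵, Jmax²⁵, TPU²⁵) by bounded trust-region least
  squares on the whole curve with Rd fixed from its separate measurement
  (a fit-Rd option exists, off by default). Multi-start over
  Vcmax ∈ {20…200 step 30} with Jmax = 1.7·Vcmax and TPU = Jmax/9 guards
  against the local minima that branch switching creates. TPU is flagged
  unidentifiable when no observation is TPU-limited at the optimum (e.g.
  curves truncated below Ci ≈ 300 µmol mol⁻¹).
* **Profile fitting.** Nonlinear least squares on the raw Na scale
  (initialization Nup = max Na, kN = 0.2), standard errors from the
  Jacobian.
* **Daily integrals** use the trapezoid rule over the hourly time stamps;
  generated days span 0–24 h inclusive so the integral covers the full day.
  Halving the time step changes daily totals by < 1 %.

## The synthetic-data generators

No field dataset ships with the package; the generators produce the three
input kinds every test and benchmark needs.

* **Weather days**: half-sine PPFD over the daylength (integral daytime
  mean = (2/π)·peak; the default clear day uses peak 1100 µmol m⁻² s⁻¹ over
  14 h, i.e. mean ≈ 700), sinusoidal air temperature between t_min and
  t_max peaking mid-afternoon, VPD from temperature at fixed 60 % relative
  humidity via the Tetens equation, constant CO₂ (400 µmol mol⁻¹). The
  default clear spring day (18–26 °C, VPD ≤ 1.35 kPa) emulates the
  conditions under which published daily canopy-exchange benchmarks for
  alfalfa were measured. Optional multiplicative PPFD noise emulates cloud
  passage; all randomness is seeded.
* **A–Ci curves**: forward FvCB evaluation on a 12-level Ci ladder spanning
  50–1400 µmol mol⁻¹ (the stepped-Ca cuvette protocol: 25 °C, PPFD 1500)
  plus Gaussian noise; the generating parameters are stored on the curve
  for recovery tests.
* **N profiles**: Beer–Lambert midpoint irradiances and the light–N profile
  plus Gaussian noise (default sd 0.15 g m⁻² in noisy fixtures), clamped
  positive.

What the generators do **not** emulate: beam/diffuse light partitioning and
sun flecks, within-canopy temperature and VPD gradients, leaf-angle effects
on interception, measurement autocorrelation in cuvette data, and leaf-age
structure. Passing recovery and benchmark tests therefore demonstrates the
numerical and statistical machinery, not predictive skill on real canopies
— that requires the field calibrations the model's parameters were designed
to accept.

## Design decisions that were genuinely open

* **Radiation scheme.** A 3-D turbid-medium model with measured leaf-angle
  distributions would resolve sunlit/shaded classes and per-stratum
  microclimate; this package deliberately uses 1-D Beer–Lambert with a
  single configurable k = 0.8 and leaf-level PPFD = k·I₀·e^(−k·L) (mean
  absorbed flux per unit leaf area). The upscaling logic, not the radiation
  solver, is the contribution; the simplification overestimates daily
  assimilation of dense canopies by roughly 15–20 % against published
  field benchmarks and shifts the N-saturation point of the response curve
  upward by about one 0.1-NNI grid step.
* **Saturation rule.** "The canopy stops responding to N" is operationalized
  as the smallest grid NNI whose daily assimilation is within 2 % of the
  grid maximum.
* **Monotonicity of the N response.** Daily totals are *saturating*, not
  strictly monotone, in NNI: night respiration scales with leaf N, so past
  saturation the 24-h integral can dip by ~0.01 %. Tests assert the
  saturating shape (strict rise below the saturation point, plateau within
  2 % above) rather than global monotonicity.
* **Boundary layer.** Leaf-surface CO₂ is taken equal to Ca (cuvette-style
  coupling); the stomatal call accepts Cs separately so a boundary-layer
  term can be added without API change.

## Problem sizes

The bundled benchmarks run a 25-record hourly day over 8 strata (200
coupled solves per day; the 12-point NNI sweep is 2 400), 200 seeded A–Ci
recovery replicates and 1 000 random solver-closure draws — sizes chosen so
the full suite exercises every code path in well under a minute while
keeping Monte-Carlo medians stable.

## Known limitations

* Calibration constants are alfalfa-specific defaults; other species need
  their own dilution curve, profile calibration and Na regressions.
* No water-stress modulation of stomata, no leaf energy balance (leaf
  temperature is an input), no root/nodule carbon costs: simulated daily
  exchange is net *aboveground* exchange.
* The two-parameter light–N profile can lack flexibility for species with
  strong leaf-age gradients; alfalfa shows little age dependence, which is
  why the formalism fits it well.
* At very low Na the linear capacity regressions predict negative values;
  they are clamped to 0 (with a warning), making such leaves inert rather
  than physically degrading gracefully.
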