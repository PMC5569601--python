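# Methods

## Model

The stomach is a continuously stirred compartment holding three masses:
nutrient `StomN` [g], non-nutrient liquid `Stomliq` [g] and thickener
(locust bean gum) `StomLBG` [g].  All three empty with the same rate
constant γ [1/s]; liquid additionally receives gastric secretions:

    dStomN/dt   = −γ·StomN
    dStomliq/dt = Ksec(μ) − γ·Stomliq
    dStomLBG/dt = −γ·StomLBG

Chyme viscosity is a power law in thickener concentration,
μ = a_L·C^b_L, with C = StomLBG / (Stomliq/ρw).  **Concentration unit:**
C is expressed in g/100 ml (ρw = 1 g/ml by default).  This is the unit in
which the default coefficients (a_L = 2, b_L = 4.21) reproduce both
anchor points of the rheology data this law descends from (1 g/100 ml ↔
2 Pa s and 1.5 g/100 ml ↔ 11 Pa s); the nominal "Pa s m³/g" labelling of
a_L is dimensionally inconsistent with a non-integer exponent, so the
package fixes the convention and documents it here.

Secretion responds to viscosity as `Ksec = λs·μ^b + Sb` [g/s], with Sb
the basal rate.  Secreted liquid has the density of water.

The emptied nutrient enters a 1-D intestinal lumen of length L = 2.85 m
as a point bolus at z = l₀ and is transported by advection at
ū = 1.7×10⁻⁴ m/s with first-order uptake Ka [1/s].  The absorption rate
`A(t) = ∫₀ᴸ Ka·S dz` feeds back on emptying through the duodenal brake:

    γ = 0        if A > Amax      (logical switch)
    γ = γ₀ / (1 + exp(τA·(A − Amax)))   (smooth switch)

The smooth form equals γ₀/2 exactly at A = Amax, is monotone
non-increasing in A, and converges to the logical switch as τA → ∞ (the
default τA = 5×10⁶ s/g makes the transition band ≈ 10⁻⁵ g/s wide).  The
exponent is clipped at ±700 and the exact limits 0/γ₀ are returned
outside the clip window, so the switch never overflows.

γ₀ itself is either a fixed constant or one of five candidate laws — the
two-term linear combinations of viscosity μ, total gastric volume
V = Stomtot/ρw [m³] and secretion rate Ksec:

    m_μ·μ + m_s·V,   m_s·V + C1,   m_μ·μ + C1,
    m_sec·Ksec + C1,   m_sec·Ksec + m_s·V

Candidate laws are compared on equal data by AIC = n·ln(SSE/n) + 2p and
relative likelihoods exp((AIC_min − AIC_i)/2).

### Assumptions and scope

Perfect gastric mixing (most accurate for low-viscosity liquid meals);
instantaneous meal consumption; Newtonian, concentration-set viscosity
with no enzymatic thinning; a single spatially uniform Ka; no cephalic
or intestinal secretion phases; no hormone or glucose–insulin coupling.
Emptied liquid and thickener are not tracked in the intestine — only
nutrient participates in the feedback.  The brake acts on nutrient mass
rate (g/s); caloric contents are metadata only.

## Numerics

Forward Euler in time; backward (upwind) differences in space for the
advection term.  Zero-gradient conditions at both ends of the intestinal
domain: at the inlet this annihilates the advective term (the inlet node
stays empty — bolus injection is clamped to interior nodes), at the
outlet the upwind flux ū·S[-1] leaves the domain as outflow.  Per step,

    ΔM_lumen = injected − absorbed − outflow

holds to round-off by construction (absorbed mass is the rectangle-rule
sum the scheme itself removes), so global nutrient bookkeeping
(stomach + lumen + absorbed + outflow = input) is exact; tests assert
~1e-15 relative.  Stability requires the CFL bound ū·dt/dz ≤ 1 and the
reaction bound Ka·dt < 1 (positivity additionally needs their sum ≤ 1);
violations raise an error naming the admissible dt.  The simulator
halves dt and retries (up to 8 times, logged) if a step produces a
negative mass or NaN.

Coupling order within a step: rates (concentration → viscosity →
secretion → γ₀), then A from the previous step's field (explicit
coupling), then the gastric Euler update, then injection and the
transport step.  The brake's trigger time therefore shifts by O(dt);
defaults use dt = 1 s for coupled runs (dt = 0.1 s reproduces the
analytic exponential limit to 3×10⁻⁵).

**Lumped transport reduction.**  Until material reaches the distal end
(t < (L−l₀)/ū ≈ 277 min) the discrete upwind scheme's total mass obeys
exactly `dM/dt = inflow − Ka·M`, and the trapezoidal A(t) equals Ka·M
because both boundary nodes are empty.  The fitting and Monte-Carlo
paths integrate this scalar recurrence instead of the field (~100×
faster); a test asserts equality with the PDE path to 1e-10.  This is an
exact reduction, not an approximation, and is refused for horizons
beyond the transit time.

Default grid: 150 cells (dz = 1.9 cm) for coupled runs; a
grid-convergence test shows halving dz and dt moves 60-min cumulative
absorption by <1%.  l₀ defaults to 0.025 m (a ~65 ml spherical bolus);
results are insensitive to l₀ within [0.01, 0.05] m because injection
position only delays outflow, which the feedback never sees before the
transit time.

## Estimation

**Brake model.**  Unweighted least squares of simulated gastric nutrient
against observed mass (or fraction-of-initial) series over any subset of
{γ₀, Amax, Ka, StomN0}.  Parameters are optimised in log10 space (all
are positive rates) with a bounded trust-region solver.  The hard switch
makes the objective piecewise flat in (Amax, Ka) whenever a candidate
never engages the brake, so every start runs a **continuation ladder in
switch sharpness**: the sigmoid is fitted at τA = 5×10², then 5×10³,
5×10⁴, then the target τA, warm-starting each stage.  This restores
gradient information far from the optimum; from a 2×-perturbed start the
noise-free inverse problem returns all three rates to <0.1%.  Fitting
always uses the smooth switch; simulation defaults to the logical one.
Multi-start (seeded log-uniform draws within bounds, default 10) guards
against residual local minima; non-convergence is flagged on the result,
never raised.  A fit whose optimal trajectory never approaches Amax is
flagged "A_max unidentifiable".

**Secretion model.**  The composite objective for a panel of non-nutrient
meals i with initial viscosity μ0_i and liquid load liq0_i:

    Obj = Σ_ij ((μ_exp,ij − μ_sim,ij)/μ0_i)² + Σ_i 2·(0.5 − Stomtot(t½_i)/liq0_i)²

implemented as a residual vector (the half-time terms carry a √2
factor).  Note the printed normalisation divides Stomtot by liq0 while
Stomtot(0) also contains the thickener; the synthetic generator therefore
records its "measured" half-time as the crossing of liq0/2, the
definition under which a model scored against its own data gives exactly
zero.  Each candidate γ₀ law is fitted with the same protocol (log-space
trust region; starts = a data-informed guess sizing each γ₀ term to
contribute half of ln2/t̄½, the geometric bound centre, and seeded random
draws) and ranked by AIC with n = number of residual components and
p = 5 for every form.

## Sensitivity analysis

One-sided finite differences with fractional perturbation ε (default 1%):

    S*(t) = [f(θ(1+ε)) − f(θ)] / (ε·f0),   f = gastric nutrient mass,

normalised by f0 = the meal input mass (configurable).  Nominal and
perturbed runs share the grid and switch mode (logical by default, which
preserves the spike morphology at brake-switching times).  Whenever the
brake never engages, S* for Amax and Ka is identically zero — the
zero-pattern is itself the diagnostic.

## Monte-Carlo uncertainty

Observations are perturbed with seeded noise whose per-point scale is
the replicate standard deviation attached to the data; the model is
re-fitted (warm-started from the unperturbed optimum by default) and the
parameter samples summarised as mean ± 2σ bounds (flooring at zero is
available but off by default, since downstream fitting treats the
bounds as a search box, not a physical constraint).  Noise law: uniform
on [−sd, +sd] by default — the scales are quoted as maximum deviations
from the mean — with Gaussian as an option.  Default 5000 iterations;
identical seed + data reproduce the result bit-for-bit.

## Synthetic data

Published fits of this model family target datasets that exist only as
figures, so the generator fabricates statistically matched stand-ins:

* **Glucose-meal conditions "a"–"h"**: simulate the packaged parameter
  sets (15–114 g glucose; condition "a" has no reported brake constants
  and runs brake-free, optionally borrowing another condition's Amax/Ka
  for sensitivity probing), sample at 10-min intervals to 60 min, add
  seeded additive Gaussian noise with per-time SDs of 6–17% of the
  initial mass (the packaged replicate-SD table, interpreted as percent
  of initial), floor at zero.
* **Non-nutrient viscosity panels**: meals defined by initial viscosity
  (inverting the power law for the thickener load; 500 g liquid load, a
  typical test-meal volume), viscosity sampled 0–60 min, the
  total-content half-time recorded as metadata; optional multiplicative
  log-normal viscosity noise (σ = 0.1 in the recovery experiments,
  reflecting the large but unquantified error bars typical of in-vivo
  viscometry).
* **Combined meals LVN/HVN/LVC/HVC**: nutrient loads of 80 g (nutrient
  meals) and 16 g (controls) in 500 g liquid, with initial viscosities
  0.06 (low) and 11 Pa s (high) — the extremes of the range over which
  the rheology law was calibrated; the true high-viscosity meals were
  nearer 30 Pa s, outside that law's support.

What passing tests on these data do **not** show: robustness to the
non-Gaussian, serially correlated noise of real gastric measurements; to
meal-to-meal rheology deviations from the single power law; or to
between-subject parameter variability — the generator draws one
parameter set per scenario.

## Problem sizes and experiment designs

The packaged verification experiments use: dt = 0.1 s for the analytic
limit;
dt = 1 s / 150 cells for coupled preset runs (horizons 2–6 h); the
noise-free recovery fit on a 5-min/120-min sampling grid; 50 seeded
replicates for both the noisy-recovery and model-selection experiments
(selection at dt = 10 s with 3 starts per form); 4-meal viscosity panels
{0.06, 2, 5.6, 11} Pa s; and glucose loads {20, 40, 80} g for the
half-time predictions.

## Known limitations

* The brake is bang-bang at the step scale: the simulated "linear" phase
  is a dt-resolution sawtooth whose mean slope is −Amax; trigger times
  shift by O(dt).
* Identifiability is sharply regime-dependent.  When the brake never or
  barely engages, Amax and Ka are flat directions (flagged); when it
  engages before the first sample, γ₀ is hidden.  At the packaged
  replicate-noise magnitudes (10–16% of initial as 1σ) the 6-point
  10–60-min design does not constrain any of the three rates to better
  than ~50% median error — the noise-injection machinery reports this
  honestly rather than hiding it.
* The γ₀ laws are linear ansätze intended for model discrimination, not
  extrapolation; the rheology power law is calibrated only up to
  11 Pa s.
* Liquid/thickener dynamics are not conservation-checked against an
  intestinal liquid field because the model deliberately does not track
  liquid beyond the pylorus.
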