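# gastrosim

Mechanistic modelling of gastric emptying for liquid meals, coupling three
processes that jointly set how fast a meal leaves the stomach:

* a **stirred gastric compartment** (CSTR) whose nutrient content StomN
  empties at rate γ: `dStomN/dt = −γ·StomN`;
* a **1-D advective small intestine** (plug flow with first-order luminal
  uptake): `∂S/∂t = −ū·∂S/∂z − Ka·S`, fed by a point bolus at z = l₀, with
  absorption rate `A(t) = ∫ Ka·S dz`;
* the **duodenal brake**: when A(t) exceeds a ceiling `Amax` the pyloric
  sphincter closes (γ → 0), either as a hard switch or a smooth sigmoid
  `γ = γ₀ / (1 + exp(τA·(A − Amax)))`, which regulates nutrient delivery to
  the gut at a constant rate ≈ Amax;
* **viscosity-driven secretion**: chyme viscosity follows a power law in
  thickener concentration (`μ = a_L·C^b_L`), gastric secretion responds as
  `Ksec = λs·μ^b + Sb`, and the base emptying rate γ₀ can itself be a
  function of viscosity, gastric volume and/or secretion rate (five
  candidate laws, compared by AIC).

The package is aimed at researchers in food/digestion modelling who need a
reproducible implementation of this model family: a forward simulator,
nonlinear least-squares parameter estimation against emptying and
viscosity data, AIC-based selection among the candidate γ₀ laws,
finite-difference sensitivity analysis, Monte-Carlo uncertainty
quantification, and a synthetic-data generator that stands in for the
(figure-only) datasets this model class is usually fitted to.

## Worked example

Simulate a 100-g glucose drink with the packaged brake parameters
(γ₀ = 9.23×10⁻⁴ s⁻¹, Amax = 7×10⁻³ g/s, Ka = 9×10⁻⁴ s⁻¹):

```python
import numpy as np
from gastrosim import simulate, half_time, caloric_delivery_rate, NUTRIENT_ONLY
from gastrosim.synthetic import table1_preset

preset = table1_preset("d")          # 98.95 g glucose, brake enabled
tr = simulate(preset.config)

t_half = half_time(tr, NUTRIENT_ONLY) / 60
active = tr.absorption_rate > 0.95 * preset.config.feedback.A_max
window = (tr.times[active][0], tr.times[active][-1])
mean_A = caloric_delivery_rate(tr, window)

print(f"half-time: {t_half:.1f} min")
print(f"brake active from {window[0]/60:.1f} to {window[1]/60:.1f} min")
print(f"mean absorption in that window: {mean_A*1e3:.2f} mg/s "
      f"(Amax = {preset.config.feedback.A_max*1e3:.1f} mg/s)")
print(f"mass balance error: {np.abs(tr.nutrient_balance_error()).max():.2e}")
```

```
half-time: 99.6 min
brake active from 1.5 to 205.5 min
mean absorption in that window: 7.01 mg/s (Amax = 7.0 mg/s)
mass balance error: 2.73e-15
```

The brake engages within two minutes and holds intestinal delivery at
Amax, so the gastric curve falls linearly — the regulated, "constant
calories per minute" regime.  A 15-g drink (preset `"a"`) never triggers
the brake and empties as a clean exponential.

A command-line surface wraps the same functionality:

```bash
gastrosim generate --preset T1e --seed 7 --out obs.csv
gastrosim simulate --config meal.yaml --out trajectory.csv
gastrosim fit --data obs.csv --template meal.yaml --out fit.json
gastrosim select-model --data panel.csv --out ranking.json
gastrosim sensitivity --config meal.yaml --param A_max --out sens.csv
gastrosim montecarlo --data obs.csv --template meal.yaml --iters 5000 --out mc.csv
```

Every run writes a `*.manifest.yaml` provenance record (config snapshot,
seed, grid actually used, package version).

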