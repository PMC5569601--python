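# Optimal combined-model (secretion + brake) parameters for four liquid
# meals: LVN/HVN = low/high viscosity nutrient meals, LVC/HVC = low/high
# viscosity control (low nutrient) meals.
# Units: Amax_g_per_s [g/s], msec [1/g], C1_per_s [1/s],
# lambdaS [g/s per (Pa s)**b], b [-], Sb_g_per_s [g/s], Ka_per_s [1/s].
# mu0_Pa_s / glucose_g / liq0_g are the synthetic meal definitions used by
# the scenario generator (initial viscosity, nutrient load, liquid load).
LVN: {Amax_g_per_s: 1.04e-2, msec: 3.66e-4, C1_per_s: 6.77e-4, lambdaS: 4.05e-2,
      b: 1.08, Sb_g_per_s: 5.7e-3, Ka_per_s: 9.80e-3,
      mu0_Pa_s: 0.06, glucose_g: 80.0, liq0_g: 500.0}
HVN: {Amax_g_per_s: 0.98e-2, msec: 3.48e-4, C1_per_s: 4.74e-4, lambdaS: 6.17e-2,
      b: 0.40, Sb_g_per_s: 1.51e-2, Ka_per_s: 2.89e-4,
      mu0_Pa_s: 11.0, glucose_g: 80.0, liq0_g: 500.0}
LVC: {Amax_g_per_s: 1.00e-2, msec: 3.27e-4, C1_per_s: 4.69e-4, lambdaS: 6.21e-2,
      b: 0.67, Sb_g_per_s: 2.13e-2, Ka_per_s: 9.80e-3,
      mu0_Pa_s: 0.06, glucose_g: 16.0, liq0_g: 500.0}
HVC: {Amax_g_per_s: 1.01e-2, msec: 3.27e-4, C1_per_s: 5.86e-4, lambdaS: 6.21e-2,
      b: 0.42, Sb_g_per_s: 2.34e-2, Ka_per_s: 2.89e-4,
      mu0_Pa_s: 11.0, glucose_g: 16.0, liq0_g: 500.0}
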