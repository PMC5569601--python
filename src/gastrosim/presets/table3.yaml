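# Optimal secretion-model parameters for non-nutrient meals under the
# gamma0 = m_sec*K_sec + C1 emptying law, with the mean +/- 2 sigma bounds
# from a 5000-iteration Monte-Carlo noise analysis.
# Units: msec [1/g], C1_per_s [1/s], lambdaS [g/s per (Pa s)**b],
# b [-], Sb_g_per_s [g/s].
mean:  {msec: 2.5e-3,  C1_per_s: 6.58e-4, lambdaS: 1.8e-2, b: 1.5, Sb_g_per_s: 1.8e-2}
upper: {msec: 1.74e-2, C1_per_s: 8.38e-4, lambdaS: 6.21e-2, b: 2.2, Sb_g_per_s: 2.8e-2}
lower: {msec: 3.27e-4, C1_per_s: 4.69e-4, lambdaS: 1.4e-3,  b: 0.2, Sb_g_per_s: 1.4e-3}
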