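# Fitted duodenal-brake model parameters for eight glucose-meal conditions
# (a-d: 15/20/50/100 g glucose drinks; e-h: low/high glucose with low/high
# polymer).  Conditions sharing a data source share the fitted rates.
# Units: StomN0_g [g], gamma0_per_s [1/s], Amax_g_per_s [g/s], Ka_per_s [1/s].
# Condition (a) has no reported Amax/Ka: the brake never engaged there.
a: {StomN0_g: 15.03, gamma0_per_s: 1.2e-3, Amax_g_per_s: null, Ka_per_s: null}
b: {StomN0_g: 20.82, gamma0_per_s: 9.23e-4, Amax_g_per_s: 7.0e-3, Ka_per_s: 9.0e-4}
c: {StomN0_g: 54.33, gamma0_per_s: 9.23e-4, Amax_g_per_s: 7.0e-3, Ka_per_s: 9.0e-4}
d: {StomN0_g: 98.95, gamma0_per_s: 9.23e-4, Amax_g_per_s: 7.0e-3, Ka_per_s: 9.0e-4}
e: {StomN0_g: 24.74, gamma0_per_s: 9.22e-4, Amax_g_per_s: 1.0e-2, Ka_per_s: 1.7e-3}
f: {StomN0_g: 114.28, gamma0_per_s: 9.22e-4, Amax_g_per_s: 1.0e-2, Ka_per_s: 1.7e-3}
g: {StomN0_g: 23.98, gamma0_per_s: 8.98e-4, Amax_g_per_s: 1.0e-2, Ka_per_s: 4.2e-4}
h: {StomN0_g: 112.83, gamma0_per_s: 8.98e-4, Amax_g_per_s: 1.0e-2, Ka_per_s: 4.2e-4}
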