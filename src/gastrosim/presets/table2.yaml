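# Experimental replicate standard deviations for the two Monte-Carlo
# conditions (f: high glucose / low polymer, h: high glucose / high polymer),
# as percent of the initial gastric content, at 10-60 min.
time_min: [10, 20, 30, 40, 50, 60]
f: [16.1, 9.7, 9.7, 11.1, 12.4, 10.6]
h: [9.7, 6.0, 9.7, 14.3, 16.6, 16.1]
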