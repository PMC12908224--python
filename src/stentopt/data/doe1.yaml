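# Reproduce the first-DOE analysis from the packaged 43-run table:
# reduced ten-term models, predicted-range desirability, 21-point grid.
space: table1
table: fixture:table4
terms: eq5
range_mode: predicted
grid: 21
t_crit: null
seed: 0
fixed: {}
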