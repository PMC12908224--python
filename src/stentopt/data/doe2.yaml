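# Reproduce the second-DOE analysis from the packaged 15-run table:
# per-response t-screened reduced models over (w, t, SA) with NS and LA
# held at the values carried over from the first DOE.
space: doe2
table: fixture:table5
terms: auto
range_mode: predicted
grid: 21
t_crit: null
seed: 0
fixed:
  NS: 16.0
  LA: 0.4
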