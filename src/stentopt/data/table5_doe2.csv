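run,w_um,t_um,SA_mm,mean_stress_kPa,high_stress_pct,apposition_pct,pinching
1,150,150,0.7,40.08,5.01,94.08,1.24
2,50,50,0.7,17.24,0.00,79.36,1.24
3,150,50,0.7,22.89,0.16,91.81,1.23
4,100,50,0.5,22.30,0.01,93.24,1.11
5,100,150,0.5,34.09,2.40,94.80,1.12
6,100,100,0.3,35.23,1.80,96.14,1.09
7,150,50,0.3,36.55,2.32,92.47,1.36
8,100,100,0.7,23.03,0.20,94.85,1.20
9,150,150,0.3,52.11,8.70,97.18,1.07
10,150,100,0.5,39.85,4.48,94.22,1.2
11,50,50,0.3,20.48,0.00,92.31,1.39
12,100,100,0.5,29.04,0.60,96.41,1.14
13,50,150,0.7,17.25,0.00,93.44,1.26
14,50,100,0.5,19.46,0.00,93.96,1.24
15,50,150,0.3,26.97,0.05,100.00,1.09
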