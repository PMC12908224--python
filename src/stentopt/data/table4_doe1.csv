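run,w_um,t_um,NS,LA_mm,SA_mm,mean_stress_kPa,high_stress_pct,apposition_pct,pinching
1,175,175,24,0.4,2,21.41,0.06,59.15,1.53
2,250,250,32,0,0.5,71.52,17.29,93.32,1.07
3,175,175,24,0.8,1.25,29.93,1.61,76.80,1.73
4,100,250,16,0.8,2,15.57,0.01,53.63,1.31
5,100,100,16,0,2,14.54,0.00,45.42,1.30
6,100,250,16,0,0.5,39.31,3.97,97.68,1.08
7,100,100,32,0,2,14.19,0.00,14.64,1.29
8,250,250,32,0.8,0.5,69.64,18.27,94.01,1.07
9,250,250,16,0,2,29.03,1.27,82.37,1.79
10,250,100,32,0.8,2,19.42,0.11,35.28,1.51
11,100,250,16,0.8,0.5,36.86,2.96,98.05,1.08
12,250,100,16,0.8,2,22.80,0.25,67.48,1.61
13,250,100,32,0,0.5,60.75,13.66,92.54,1.27
14,250,100,32,0,2,21.13,0.12,44.50,1.57
15,175,175,16,0.4,1.25,32.52,2.65,91.05,1.63
16,250,100,32,0.8,0.5,58.26,13.40,94.45,1.28
17,175,175,24,0,1.25,29.88,1.57,68.95,1.78
18,100,175,24,0.4,1.25,19.98,0.09,58.70,1.45
19,175,175,24,0.4,0.5,53.60,9.70,93.83,1.13
20,250,100,16,0,0.5,50.75,8.42,95.88,1.25
21,250,250,32,0.8,2,23.24,0.50,49.07,1.62
22,175,250,24,0.4,1.25,32.91,2.67,72.48,1.71
23,175,175,32,0.4,1.25,27.64,1.02,58.93,1.78
24,175,100,24,0.4,1.25,25.14,0.43,58.08,1.71
25,250,100,16,0.8,0.5,53.38,10.52,96.52,1.22
26,100,250,32,0.8,2,14.61,0.00,9.36,1.24
27,250,250,16,0,0.5,61.62,13.04,95.29,1.03
28,250,250,16,0.8,2,29.69,1.60,78.62,1.72
29,175,175,24,0.4,1.25,30.12,1.68,67.97,1.81
30,100,250,32,0,2,14.84,0.00,23.15,1.26
31,250,175,24,0.4,1.25,34.47,2.92,63.25,1.93
32,250,250,32,0,2,28.56,1.99,50.49,1.67
33,100,100,32,0.8,2,14.14,0.00,21.61,1.29
34,250,100,16,0,2,22.57,0.18,68.27,1.69
35,100,100,16,0,0.5,29.56,0.57,97.10,1.20
36,100,100,16,0.8,2,14.53,0.00,56.18,1.30
37,100,100,32,0.8,0.5,32.79,0.93,96.27,1.23
38,100,250,32,0,0.5,44.65,5.12,91.71,1.15
39,100,250,32,0.8,0.5,43.85,5.36,95.03,1.16
40,100,100,16,0.8,0.5,28.94,0.40,98.05,1.15
41,100,100,32,0,0.5,34.26,1.73,92.50,1.34
42,100,250,16,0,2,16.55,0.00,48.23,1.32
43,250,250,16,0.8,0.5,58.92,12.11,94.03,1.04
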