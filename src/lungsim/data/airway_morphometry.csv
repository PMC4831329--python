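generation,branches,terminal_branches,d_mean,d_max,d_min,d_std
1,1,0,14.12,14.12,14.12,0.00
2,2,0,11.13,12.07,10.20,1.32
3,4,0,9.17,10.00,8.00,0.85
4,8,0,6.30,8.00,4.40,1.08
5,16,0,4.62,7.00,3.30,1.22
6,32,0,3.28,6.20,2.69,0.77
7,64,0,2.75,6.00,1.81,0.70
8,128,0,2.27,5.40,1.29,0.54
9,256,2,1.85,3.90,0.79,0.42
10,508,7,1.51,2.90,0.59,0.40
11,1002,56,1.23,2.59,0.50,0.37
12,1892,206,1.01,2.38,0.48,0.32
13,3372,685,0.85,2.23,0.47,0.27
14,5374,1722,0.74,2.01,0.46,0.23
15,7304,2947,0.67,1.85,0.44,0.19
16,8714,4265,0.63,1.70,0.40,0.16
17,8898,4965,0.60,1.57,0.37,0.14
18,7866,4646,0.58,1.39,0.35,0.12
19,6440,4059,0.57,1.24,0.33,0.11
20,4762,3047,0.56,1.09,0.27,0.09
21,3430,2252,0.54,0.96,0.28,0.08
22,2356,1690,0.53,0.85,0.27,0.07
23,1332,992,0.50,0.75,0.34,0.06
24,680,508,0.48,0.71,0.29,0.06
25,344,290,0.43,0.64,0.29,0.07
26,108,108,0.38,0.57,0.24,0.07
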