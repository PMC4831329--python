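frequency_hz,r_uaw,x_uaw
0.5,15.0,-318.25
1.0,15.0,-159.03
2.0,15.0,-79.33
4.0,15.0,-39.28
8.0,15.0,-18.88
16.0,15.0,-7.94
32.0,15.0,-0.95
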