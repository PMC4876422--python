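sequence,i_max_A,run1_avg_dI_A,run1_rel_pct,run2_avg_dI_A,run2_rel_pct
1,0.732,0.036,4.9,0.058,7.9
2,0.825,0.031,3.6,0.059,7.2
3,0.888,0.033,3.7,0.043,4.8
4,1.422,0.043,3.0,0.059,4.1
5,1.412,0.039,2.8,0.072,5.1
6,1.597,0.050,3.1,0.062,3.9
7,2.015,0.045,2.2,0.047,2.3
8,2.005,0.041,2.0,0.090,4.5
9,2.302,0.063,2.7,0.094,4.1
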