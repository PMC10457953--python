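variety,group,firmness_with_peel,firmness_with_peel_se,firmness_without_peel,firmness_without_peel_se,shape_index,shape_index_se,moisture,moisture_se
P1,regular,3.37,0.08,2.14,0.08,0.82,0.01,96.16,0.01
P2,regular,3.53,0.04,1.99,0.03,0.85,0.01,95.80,0.02
P3,regular,2.50,0.05,1.19,0.08,0.76,0.03,95.25,0.06
P4,regular,4.36,0.15,2.18,0.10,0.82,0.01,94.72,0.04
P5,regular,3.50,0.09,1.56,0.05,0.80,0.01,94.51,0.05
T1,tasty,2.38,0.05,0.70,0.01,0.76,0.02,93.19,0.07
T2,tasty,2.43,0.15,0.81,0.07,0.97,0.03,93.04,0.03
T3,tasty,3.63,0.08,0.82,0.04,0.78,0.02,92.00,0.04
T4,tasty,2.05,0.05,0.59,0.03,0.85,0.01,92.70,0.03
T5,tasty,2.49,0.04,0.59,0.03,0.88,0.01,90.92,0.03
Y1,cherry,2.48,0.15,1.12,0.06,0.79,0.02,93.45,0.02
Y2,cherry,2.16,0.17,1.04,0.07,0.90,0.01,94.23,0.00
Y3,cherry,3.01,0.06,1.09,0.03,0.87,0.01,93.89,0.04
Y4,cherry,2.56,0.13,1.16,0.07,0.89,0.01,93.74,0.04
Y5,cherry,2.47,0.01,1.45,0.14,1.30,0.05,92.23,0.02
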