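variety,group,flavor_score,appearance_score
P1,regular,2.85,3.48
P2,regular,2.54,2.76
P3,regular,3.81,3.87
P4,regular,4.10,4.26
P5,regular,4.15,3.70
T1,tasty,4.52,3.44
T2,tasty,4.31,3.74
T3,tasty,4.79,4.08
T4,tasty,4.48,3.73
T5,tasty,4.86,3.65
Y1,cherry,3.89,3.81
Y2,cherry,3.47,3.68
Y3,cherry,3.52,3.70
Y4,cherry,4.02,3.70
Y5,cherry,4.67,3.80
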