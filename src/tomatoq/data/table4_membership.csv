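variety,group,membership,rank
P1,regular,0.14,12
P2,regular,0.07,15
P3,regular,0.15,11
P4,regular,0.20,9
P5,regular,0.10,14
T1,tasty,0.35,4
T2,tasty,0.38,3
T3,tasty,0.30,6
T4,tasty,0.50,2
T5,tasty,0.55,1
Y1,cherry,0.15,10
Y2,cherry,0.13,13
Y3,cherry,0.28,7
Y4,cherry,0.27,8
Y5,cherry,0.31,5
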