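W1,W2,W3,W4,W5,W6,W7,W8,W9,W10,W11,W12,W13,W14,W15,W16,W17,W18,W19,W20,W21,W22,W23
1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
1,1,1,1,1,1,1,1,1,1,1,2,2,2,2,2,2,2,2,2,2,2,2
1,1,1,1,1,1,1,1,1,1,1,3,3,3,3,3,3,3,3,3,3,3,3
1,1,1,1,1,2,2,2,2,2,2,1,1,1,1,2,2,2,2,3,3,3,3
1,1,1,1,1,2,2,2,2,2,2,2,2,2,2,3,3,3,3,1,1,1,1
1,1,1,1,1,2,2,2,2,2,2,3,3,3,3,1,1,1,1,2,2,2,2
1,1,2,2,2,1,1,1,2,2,2,1,1,2,3,1,2,3,3,1,2,2,3
1,1,2,2,2,1,1,1,2,2,2,2,2,3,1,2,3,1,1,2,3,3,1
1,1,2,2,2,1,1,1,2,2,2,3,3,1,2,3,1,2,2,3,1,1,2
1,2,1,2,2,1,2,2,1,1,2,1,1,3,2,1,3,2,3,2,1,3,2
1,2,1,2,2,1,2,2,1,1,2,2,2,1,3,2,1,3,1,3,2,1,3
1,2,1,2,2,1,2,2,1,1,2,3,3,2,1,3,2,1,2,1,3,2,1
1,2,2,1,2,2,1,2,1,2,1,1,2,3,1,3,2,1,3,3,2,1,2
1,2,2,1,2,2,1,2,1,2,1,2,3,1,2,1,3,2,1,1,3,2,3
1,2,2,1,2,2,1,2,1,2,1,3,1,2,3,2,1,3,2,2,1,3,1
1,2,2,2,1,2,2,1,2,1,1,1,2,3,2,1,1,3,2,3,3,2,1
1,2,2,2,1,2,2,1,2,1,1,2,3,1,3,2,2,1,3,1,1,3,2
1,2,2,2,1,2,2,1,2,1,1,3,1,2,1,3,3,2,1,2,2,1,3
2,1,2,2,1,1,2,2,1,2,1,1,2,1,3,3,3,1,2,2,1,2,3
2,1,2,2,1,1,2,2,1,2,1,2,3,2,1,1,1,2,3,3,2,3,1
2,1,2,2,1,1,2,2,1,2,1,3,1,3,2,2,2,3,1,1,3,1,2
2,1,2,1,2,2,2,1,1,1,2,1,2,2,3,3,1,2,1,1,3,3,2
2,1,2,1,2,2,2,1,1,1,2,2,3,3,1,1,2,3,2,2,1,1,3
2,1,2,1,2,2,2,1,1,1,2,3,1,1,2,2,3,1,3,3,2,2,1
2,1,1,2,2,2,1,2,2,1,1,1,3,2,1,2,3,3,1,3,1,2,2
2,1,1,2,2,2,1,2,2,1,1,2,1,3,2,3,1,1,2,1,2,3,3
2,1,1,2,2,2,1,2,2,1,1,3,2,1,3,1,2,2,3,2,3,1,1
2,2,2,1,1,1,1,2,2,1,2,1,3,2,2,2,1,1,3,2,3,1,3
2,2,2,1,1,1,1,2,2,1,2,2,1,3,3,3,2,2,1,3,1,2,1
2,2,2,1,1,1,1,2,2,1,2,3,2,1,1,1,3,3,2,1,2,3,2
2,2,1,2,1,2,1,1,1,2,2,1,3,3,3,2,3,2,2,1,2,1,1
2,2,1,2,1,2,1,1,1,2,2,2,1,1,1,3,1,3,3,2,3,2,2
2,2,1,2,1,2,1,1,1,2,2,3,2,2,2,1,2,1,1,3,1,3,3
2,2,1,1,2,1,2,1,2,2,1,1,3,1,2,3,2,3,1,2,2,3,1
2,2,1,1,2,1,2,1,2,2,1,2,1,2,3,1,3,1,2,3,3,1,2
2,2,1,1,2,1,2,1,2,2,1,3,2,3,1,2,1,2,3,1,1,2,3
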