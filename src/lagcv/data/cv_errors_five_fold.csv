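layer1,layer2,cv_error
6,6,85.426
6,12,81.304
6,24,81.338
6,36,71.188
6,48,81.336
6,60,74.154
12,6,71.144
12,12,72.804
12,24,64.592
12,36,71.302
12,48,71.212
12,60,62.352
24,6,67.642
24,12,70.088
24,24,67.496
24,36,68.262
24,48,61.364
24,60,66.178
36,6,63.636
36,12,67.834
36,24,60.954
36,36,71.614
36,48,67.128
36,60,70.878
48,6,63.926
48,12,63.42
48,24,63.758
48,36,63.368
48,48,67.044
48,60,69.514
60,6,69.014
60,12,61.192
60,24,67.588
60,36,65.934
60,48,61.574
60,60,61.466
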