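layer1,layer2,cv_error
6,6,79.326
6,12,81.838
6,24,81.836
6,36,80.534
6,48,76.284
6,60,81.838
12,6,74.936
12,12,82.5
12,24,82.082
12,36,81.83
12,48,71.636
12,60,81.82
24,6,85.95
24,12,81.832
24,24,72.872
24,36,81.844
24,48,69.3
24,60,69.16
36,6,71.988
36,12,81.848
36,24,81.85
36,36,81.844
36,48,82.026
36,60,81.828
48,6,81.822
48,12,81.578
48,24,81.85
48,36,81.832
48,48,81.826
48,60,81.838
60,6,81.854
60,12,81.836
60,24,81.826
60,36,81.826
60,48,81.838
60,60,81.832
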