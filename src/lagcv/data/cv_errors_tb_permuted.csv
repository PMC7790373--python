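layer1,layer2,cv_error
6,6,81.21
6,12,82.794
6,24,82.792
6,36,81.3
6,48,76.752
6,60,82.802
12,6,78.752
12,12,78.556
12,24,82.784
12,36,82.794
12,48,84.75
12,60,82.792
24,6,90.82
24,12,82.794
24,24,81.772
24,36,82.78
24,48,89.164
24,60,91.764
36,6,93.57
36,12,82.774
36,24,82.778
36,36,82.798
36,48,82.774
36,60,82.788
48,6,82.768
48,12,82.792
48,24,82.778
48,36,82.784
48,48,82.804
48,60,82.782
60,6,82.774
60,12,82.772
60,24,82.782
60,36,82.774
60,48,82.802
60,60,82.772
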