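layer1,layer2,cv_error
6,6,83.612
6,12,81.4
6,24,81.404
6,36,79.8
6,48,79.838
6,60,81.4
12,6,75.81
12,12,94.086
12,24,84.55
12,36,81.4
12,48,76.932
12,60,81.378
24,6,84.882
24,12,81.396
24,24,89.572
24,36,84.03
24,48,87.98
24,60,78.13
36,6,80.996
36,12,81.394
36,24,81.392
36,36,81.4
36,48,81.396
36,60,81.392
48,6,81.396
48,12,80.496
48,24,81.394
48,36,81.402
48,48,83.042
48,60,81.396
60,6,81.398
60,12,81.398
60,24,81.398
60,36,81.394
60,48,81.402
60,60,81.394
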