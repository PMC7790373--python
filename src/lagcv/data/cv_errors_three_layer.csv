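scheme,layer1,layer2,layer3,cv_error,cv_error_permuted,pr
five_fold,12,12,12,67.294,81.4,0.83
five_fold,36,36,36,71.294,81.394,0.88
five_fold,60,60,60,59.504,81.392,0.73
lobo,12,12,12,64.918,81.83,0.79
lobo,36,36,36,69.642,81.844,0.85
lobo,60,60,60,54.762,81.834,0.67
tb,12,12,12,76.188,82.79,0.92
tb,36,36,36,72.49,82.788,0.88
tb,60,60,60,65.626,82.806,0.79
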