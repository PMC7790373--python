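layer1,layer2,cv_error
6,6,77.44
6,12,82.932
6,24,82.916
6,36,64.442
6,48,82.942
6,60,67.37
12,6,83.714
12,12,74.006
12,24,59.972
12,36,64.262
12,48,70.766
12,60,58.836
24,6,64.904
24,12,70.86
24,24,56.826
24,36,64.104
24,48,56.208
24,60,54.442
36,6,61.646
36,12,65.514
36,24,53.66
36,36,66.154
36,48,66.034
36,60,67.444
48,6,72.152
48,12,58.502
48,24,62.582
48,36,62.962
48,48,61.992
48,60,66.506
60,6,65.538
60,12,55.306
60,24,69.122
60,36,63.274
60,48,59.88
60,60,59.774
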