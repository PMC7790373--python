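layer1,layer2,cv_error
6,6,105.074
6,12,86.83
6,24,86.796
6,36,84.622
6,48,86.836
6,60,75.072
12,6,120.94
12,12,91.162
12,24,81.738
12,36,75.194
12,48,71.402
12,60,71.892
24,6,86.708
24,12,74.842
24,24,81.502
24,36,76.46
24,48,76.684
24,60,71.73
36,6,65.936
36,12,75.728
36,24,74.366
36,36,72.372
36,48,120.144
36,60,92.18
48,6,82.374
48,12,72.404
48,24,81.142
48,36,74.824
48,48,82.146
48,60,78.956
60,6,73.674
60,12,66.702
60,24,76.936
60,36,69.528
60,48,74.32
60,60,78.148
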