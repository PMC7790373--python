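scheme,layer1,layer2,pr
five_fold,6,6,1.000
five_fold,6,12,0.999
five_fold,6,24,0.999
five_fold,6,36,0.892
five_fold,6,48,1.000
five_fold,6,60,0.911
five_fold,12,6,0.938
five_fold,12,12,0.774
five_fold,12,24,0.764
five_fold,12,36,0.876
five_fold,12,48,0.926
five_fold,12,60,0.766
five_fold,24,6,0.797
five_fold,24,12,0.861
five_fold,24,24,0.754
five_fold,24,36,0.812
five_fold,24,48,0.697
five_fold,24,60,0.847
five_fold,36,6,0.786
five_fold,36,12,0.833
five_fold,36,24,0.749
five_fold,36,36,0.880
five_fold,36,48,0.825
five_fold,36,60,0.871
five_fold,48,6,0.785
five_fold,48,12,0.788
five_fold,48,24,0.783
five_fold,48,36,0.778
five_fold,48,48,0.807
five_fold,48,60,0.854
five_fold,60,6,0.848
five_fold,60,12,0.752
five_fold,60,24,0.830
five_fold,60,36,0.810
five_fold,60,48,0.756
five_fold,60,60,0.755
lobo,6,6,0.976
lobo,6,12,1.000
lobo,6,24,1.000
lobo,6,36,0.800
lobo,6,48,1.000
lobo,6,60,0.823
lobo,12,6,1.000
lobo,12,12,0.897
lobo,12,24,0.731
lobo,12,36,0.785
lobo,12,48,0.988
lobo,12,60,0.719
lobo,24,6,0.755
lobo,24,12,0.866
lobo,24,24,0.780
lobo,24,36,0.783
lobo,24,48,0.811
lobo,24,60,0.787
lobo,36,6,0.856
lobo,36,12,0.800
lobo,36,24,0.656
lobo,36,36,0.808
lobo,36,48,0.805
lobo,36,60,0.824
lobo,48,6,0.882
lobo,48,12,0.717
lobo,48,24,0.765
lobo,48,36,0.769
lobo,48,48,0.758
lobo,48,60,0.813
lobo,60,6,0.801
lobo,60,12,0.676
lobo,60,24,0.845
lobo,60,36,0.773
lobo,60,48,0.732
lobo,60,60,0.730
tb,6,6,1.000
tb,6,12,1.000
tb,6,24,1.000
tb,6,36,1.000
tb,6,48,1.000
tb,6,60,0.907
tb,12,6,1.000
tb,12,12,1.000
tb,12,24,0.987
tb,12,36,0.908
tb,12,48,0.843
tb,12,60,0.868
tb,24,6,0.955
tb,24,12,0.904
tb,24,24,0.997
tb,24,36,0.924
tb,24,48,0.860
tb,24,60,0.782
tb,36,6,0.705
tb,36,12,0.915
tb,36,24,0.898
tb,36,36,0.874
tb,36,48,1.000
tb,36,60,1.000
tb,48,6,0.995
tb,48,12,0.875
tb,48,24,0.980
tb,48,36,0.904
tb,48,48,0.992
tb,48,60,0.954
tb,60,6,0.890
tb,60,12,0.806
tb,60,24,0.929
tb,60,36,0.840
tb,60,48,0.898
tb,60,60,0.944
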