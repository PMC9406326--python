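fold,F1,Precision,Recall,Accuracy,Specificity
1,0.86960,0.86078,0.87854,0.66834,0.66298
2,0.88730,0.90188,0.87316,0.69347,0.66127
3,0.87180,0.86158,0.88229,0.67337,0.64810
4,0.86750,0.86807,0.86694,0.73869,0.67762
5,0.88280,0.90251,0.86399,0.68342,0.63900
6,0.87890,0.87545,0.88247,0.68342,0.63624
7,0.87910,0.87691,0.88128,0.66332,0.67711
8,0.86120,0.87116,0.85153,0.69849,0.67995
9,0.87420,0.88535,0.86323,0.66834,0.67312
10,0.88780,0.88409,0.89156,0.65829,0.67185
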