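fold,F1,Precision,Recall,Accuracy,Specificity
1,0.81818,0.90000,0.75000,0.80000,0.87500
2,0.82353,0.87500,0.77778,0.70000,0.00000
3,0.81250,0.86667,0.76471,0.70000,0.33333
4,0.81250,0.86667,0.76471,0.70000,0.33333
5,0.76923,0.83333,0.71429,0.70000,0.66667
6,0.81250,0.86667,0.76471,0.70000,0.33333
7,0.81250,0.86667,0.76471,0.70000,0.33333
8,0.80000,0.85714,0.75000,0.70000,0.50000
9,0.78571,0.84615,0.73333,0.70000,0.60000
10,0.81250,0.86667,0.76471,0.70000,0.33333
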