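fold,F1,Precision,Recall,Accuracy,Specificity
1,0.90909,0.93750,0.88235,0.88235,0.66667
2,0.90909,0.93750,0.88235,0.88235,0.66667
3,0.86667,0.92857,0.81250,0.81250,0.75000
4,0.87500,0.93333,0.82353,0.82353,0.66667
5,0.84615,0.91667,0.78571,0.78571,0.83333
6,0.89655,0.92857,0.86667,0.86667,0.80000
7,0.90323,0.93333,0.87500,0.87500,0.75000
8,0.91429,0.94118,0.88889,0.88889,0.50000
9,0.86667,0.92857,0.81250,0.81250,0.75000
10,0.88889,0.92308,0.85714,0.85714,0.83333
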