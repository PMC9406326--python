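fold,F1,Precision,Recall,Accuracy,Specificity
1,0.74510,0.82609,0.67857,0.72340,0.78947
2,0.76923,0.83333,0.71429,0.73913,0.77778
3,0.76667,0.85185,0.69697,0.69565,0.69231
4,0.78788,0.83871,0.74286,0.69565,0.54545
5,0.75862,0.84615,0.68750,0.69565,0.71429
6,0.75000,0.82759,0.68571,0.65217,0.54545
7,0.80702,0.85185,0.76667,0.76087,0.75000
8,0.76471,0.83871,0.70270,0.65217,0.44444
9,0.77966,0.85185,0.71875,0.71739,0.71429
10,0.80702,0.85185,0.76667,0.76087,0.75000
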