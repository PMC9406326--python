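fold,F1,Precision,Recall,Accuracy,Specificity
1,0.82540,0.89655,0.76471,0.76596,0.76923
2,0.87273,0.92308,0.82759,0.84783,0.88235
3,0.80702,0.88462,0.74194,0.76087,0.80000
4,0.88889,0.92308,0.85714,0.86957,0.88889
5,0.81967,0.89286,0.75758,0.76087,0.76923
6,0.84211,0.88889,0.80000,0.80435,0.81250
7,0.83582,0.90323,0.77778,0.76087,0.70000
8,0.86792,0.92000,0.82143,0.84783,0.88889
9,0.83077,0.90000,0.77143,0.76087,0.72727
10,0.83582,0.90323,0.77778,0.76087,0.70000
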