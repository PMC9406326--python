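fold,F1,Precision,Recall,Accuracy,Specificity
1,0.90410,0.89411,0.914328,0.77889,0.73888
2,0.91490,0.90734,0.922586,0.76382,0.74650
3,0.93140,0.93938,0.923584,0.79899,0.75860
4,0.91270,0.91895,0.906528,0.80402,0.73957
5,0.92270,0.94316,0.903088,0.79397,0.78863
6,0.93140,0.93279,0.930083,0.79397,0.74694
7,0.89580,0.89813,0.893478,0.77387,0.75531
8,0.90550,0.92049,0.890943,0.76884,0.75336
9,0.91700,0.90336,0.931074,0.80402,0.74156
10,0.93320,0.94119,0.925291,0.82412,0.76313
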