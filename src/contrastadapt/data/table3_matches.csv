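observer_id,condition,upper_contrast,mean_match,sd_match,n
1,control,0.0200,0.0248,0.0046,10
1,control,0.0285,0.0316,0.0081,10
1,control,0.0407,0.0438,0.0137,10
1,control,0.0581,0.0618,0.0136,10
1,control,0.0829,0.0839,0.0230,10
1,control,0.1183,0.1105,0.0198,10
1,control,0.1688,0.1614,0.0422,10
1,control,0.2409,0.2251,0.0536,10
1,control,0.3438,0.3088,0.0438,10
1,control,0.4906,0.4746,0.0535,10
1,control,0.7000,0.7282,0.0601,10
1,adaptation,0.1183,0.0622,0.0264,10
1,adaptation,0.1688,0.0775,0.0314,10
1,adaptation,0.2409,0.1457,0.0461,10
1,adaptation,0.3438,0.2013,0.0718,10
1,adaptation,0.4906,0.3906,0.1204,10
1,adaptation,0.7000,0.6866,0.0798,10
2,control,0.0200,0.0198,0.0064,10
2,control,0.0285,0.0249,0.0074,10
2,control,0.0407,0.0382,0.0124,10
2,control,0.0581,0.0610,0.0174,10
2,control,0.0829,0.0707,0.0238,10
2,control,0.1183,0.1061,0.0249,10
2,control,0.1688,0.1734,0.0512,10
2,control,0.2409,0.2510,0.0399,10
2,control,0.3438,0.3186,0.0438,10
2,control,0.4906,0.4467,0.0563,10
2,control,0.7000,0.6638,0.1069,10
2,adaptation,0.1183,0.0585,0.0324,10
2,adaptation,0.1688,0.0641,0.0245,10
2,adaptation,0.2409,0.1247,0.0440,10
2,adaptation,0.3438,0.2059,0.0531,10
2,adaptation,0.4906,0.3563,0.0579,10
2,adaptation,0.7000,0.5698,0.1082,10
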