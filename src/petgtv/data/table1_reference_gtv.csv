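patient,fdg_cm3,ch_cm3
1,29.18,41.20
2,18.09,36.38
3,19.90,39.83
5,45.41,57.11
6,69.51,104.03
7,22.15,42.28
8,41.86,58.44
9,72.58,99.98
10,43.87,49.96
11,36.04,63.20
12,22.59,35.69
14,54.15,65.70
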