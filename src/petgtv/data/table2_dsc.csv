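modality,observer,comparator,dsc
FDG,A,Ref,0.77
FDG,B,A,0.75
FDG,B,Ref,0.81
FDG,C,A,0.71
FDG,C,B,0.82
FDG,C,Ref,0.83
FDG,D,A,0.78
FDG,D,B,0.76
FDG,D,C,0.80
FDG,D,Ref,0.85
CH,A,Ref,0.92
CH,B,A,0.86
CH,B,Ref,0.95
CH,C,A,0.88
CH,C,B,0.92
CH,C,Ref,0.92
CH,D,A,0.91
CH,D,B,0.89
CH,D,C,0.89
CH,D,Ref,0.97
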