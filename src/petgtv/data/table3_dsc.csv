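method,fdg_vs_ref,ch_vs_ref
SUV15,0.28,0.38
SUV30,0.35,0.42
SUV40,0.36,0.44
RG,0.34,0.62
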