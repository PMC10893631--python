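target,actives,decoys
VEGFR2,26,801
FGFR1,20,600
BRAF,27,913
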