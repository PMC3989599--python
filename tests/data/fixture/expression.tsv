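gene_id	expr_0_2	expr_2_4
g0000_ear	0.573	165.441
g0001_mat	582.394	597.136
g0002_mat	776.806	314.098
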