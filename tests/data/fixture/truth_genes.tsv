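gene_id	class
g0000_ear	early_zygotic
g0001_mat	maternal
g0002_mat	maternal
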