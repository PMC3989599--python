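boundary	gene_id	gene_class	intron_len	size_bin	n_spliced	n_unspliced	n_mis_spliced	informative	retention_pct
chrS:384-866:+	g0000_ear	early_zygotic	482	100to500	5	0	0	False	
chrS:1081-1576:+	g0000_ear	early_zygotic	495	100to500	19	3	0	True	13.636364
chrS:2574-2643:-	g0001_mat	maternal	69	lt100	19	0	0	True	0.000000
chrS:2841-2926:-	g0001_mat	maternal	85	lt100	10	3	0	True	23.076923
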