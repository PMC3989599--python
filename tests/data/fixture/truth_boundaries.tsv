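chrom	intron_start	intron_end	strand	gene_id	p	mis_rate	mis_shift	canonical	unsafe	n_retained	n_spliced	n_mis
chrS	384	866	+	g0000_ear	0.0000	0.0000	11	1	0	0	25	0
chrS	1081	1576	+	g0000_ear	0.5000	0.0000	12	1	0	11	14	0
chrS	2574	2643	-	g0001_mat	0.0000	0.0000	5	1	0	0	25	0
chrS	2841	2926	-	g0001_mat	0.5000	0.0000	7	1	0	11	14	0
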