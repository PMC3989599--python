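chrom	intron_start	intron_end	strand	gene_id	intron_len	upstream_exon_len	downstream_exon_len	safe
chrS	384	866	+	g0000_ear	482	284	215	1
chrS	1081	1576	+	g0000_ear	495	215	249	1
chrS	2574	2643	-	g0001_mat	69	198	249	1
chrS	2841	2926	-	g0001_mat	85	271	198	1
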