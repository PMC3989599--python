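chrS	sim	exon	101	384	.	+	.	gene_id "g0000_ear"; transcript_id "t1";
chrS	sim	exon	867	1081	.	+	.	gene_id "g0000_ear"; transcript_id "t1";
chrS	sim	exon	1577	1825	.	+	.	gene_id "g0000_ear"; transcript_id "t1";
chrS	sim	exon	2326	2574	.	-	.	gene_id "g0001_mat"; transcript_id "t1";
chrS	sim	exon	2644	2841	.	-	.	gene_id "g0001_mat"; transcript_id "t1";
chrS	sim	exon	2927	3197	.	-	.	gene_id "g0001_mat"; transcript_id "t1";
chrS	sim	exon	3698	4820	.	-	.	gene_id "g0002_mat"; transcript_id "t1";
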