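chrK	exonskip	start_codon	1	3	.	+	0	gene_id "KrasToy"; transcript_id "KrasToy.t1";
chrK	exonskip	exon	1	200	.	+	.	gene_id "KrasToy"; transcript_id "KrasToy.t1"; exon_number "1";
chrK	exonskip	exon	501	622	.	+	.	gene_id "KrasToy"; transcript_id "KrasToy.t1"; exon_number "2";
chrK	exonskip	exon	1001	1400	.	+	.	gene_id "KrasToy"; transcript_id "KrasToy.t1"; exon_number "3";
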