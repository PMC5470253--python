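chrD	exonskip	start_codon	1	3	.	+	0	gene_id "DmdToy"; transcript_id "DmdToy.t1";
chrD	exonskip	exon	1	300	.	+	.	gene_id "DmdToy"; transcript_id "DmdToy.t1"; exon_number "22";
chrD	exonskip	exon	1001	1213	.	+	.	gene_id "DmdToy"; transcript_id "DmdToy.t1"; exon_number "23";
chrD	exonskip	exon	2001	2300	.	+	.	gene_id "DmdToy"; transcript_id "DmdToy.t1"; exon_number "24";
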