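chrC	exonskip	start_codon	1	3	.	+	0	gene_id "Ctnnb1Toy"; transcript_id "Ctnnb1Toy.t1";
chrC	exonskip	exon	1	150	.	+	.	gene_id "Ctnnb1Toy"; transcript_id "Ctnnb1Toy.t1"; exon_number "2";
chrC	exonskip	exon	401	628	.	+	.	gene_id "Ctnnb1Toy"; transcript_id "Ctnnb1Toy.t1"; exon_number "3";
chrC	exonskip	exon	901	1084	.	+	.	gene_id "Ctnnb1Toy"; transcript_id "Ctnnb1Toy.t1"; exon_number "4";
chrC	exonskip	exon	1301	1399	.	+	.	gene_id "Ctnnb1Toy"; transcript_id "Ctnnb1Toy.t1"; exon_number "5";
chrC	exonskip	exon	1601	1750	.	+	.	gene_id "Ctnnb1Toy"; transcript_id "Ctnnb1Toy.t1"; exon_number "6";
chrC	exonskip	exon	2001	2200	.	+	.	gene_id "Ctnnb1Toy"; transcript_id "Ctnnb1Toy.t1"; exon_number "7";
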