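chrP	exonskip	start_codon	1	3	.	+	0	gene_id "P65Toy"; transcript_id "P65Toy.t1";
chrP	exonskip	exon	1	150	.	+	.	gene_id "P65Toy"; transcript_id "P65Toy.t1"; exon_number "4";
chrP	exonskip	exon	1001	1100	.	+	.	gene_id "P65Toy"; transcript_id "P65Toy.t1"; exon_number "5";
chrP	exonskip	exon	1501	1600	.	+	.	gene_id "P65Toy"; transcript_id "P65Toy.t1"; exon_number "6";
chrP	exonskip	exon	2101	2200	.	+	.	gene_id "P65Toy"; transcript_id "P65Toy.t1"; exon_number "7";
chrP	exonskip	exon	3001	3150	.	+	.	gene_id "P65Toy"; transcript_id "P65Toy.t1"; exon_number "8";
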