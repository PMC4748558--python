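gene_a	chrom_a	start_a	end_a	strand_a	gene_b	chrom_b	start_b	end_b	strand_b	source
AHCTF1	chr1	247002400	247094726	-	NAAA	chr4	76831808	76862166	-	Kangaspeska
STARD3	chr17	37793333	37820454	+	DOK5	chr20	53092266	53267710	+	Edgren
VAPB	chr20	56964175	57026157	+	IKZF3	chr17	37913968	38020441	-	Edgren
TRPC4AP	chr20	33590207	33680618	-	MRPL45	chr17	36452989	36479101	+	Kangaspeska
RAB22A	chr20	56884771	56942563	+	MYO9B	chr19	17186591	17324104	+	Edgren
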