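name	pct_loh	loh_bp	loh_variants
chr1	0.0	0	0
chr2	0.0	0	0
chr3	40.4	80000000	1573295
chr4	0.0	0	0
chr5	0.0	0	0
chr6	0.0	0	0
chr7	0.0	0	0
chr8	34.2	50000000	987501
chr9	24.8	35000000	639910
chr10	41.0	55534747	1069355
chr11	40.7	55006516	1062289
chr12	0.0	0	0
chr13	100.0	115169878	1814242
chr14	0.0	0	0
chr15	75.0	76898544	1183010
chr16	0.0	0	0
chr17	0.0	0	0
chr18	0.0	0	0
chr19	0.0	0	0
chr20	0.0	0	0
chr21	0.0	0	0
chr22	100.0	51304566	745778
chrX	100.0	155270560	2174952
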