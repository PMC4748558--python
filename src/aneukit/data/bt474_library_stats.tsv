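library	snv_total	hom_snv	het_snv
STD	3241932	1531723	1635402
LFR1	2856624	1382653	1195290
LFR2	2890506	1241444	1239735
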