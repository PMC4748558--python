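name	length_bp	variant_count	centromere_mbp
chr1	249250621	4401091	125
chr2	243199373	4607702	93.3
chr3	198022430	3894345	91
chr4	191154276	3673892	50.4
chr5	180915260	3436667	48.4
chr6	171115067	3360890	61
chr7	159138663	3045992	59.9
chr8	146364022	2890692	45.6
chr9	141213431	2581827	49
chr10	135534747	2609802	40.2
chr11	135006516	2607254	53.7
chr12	133851895	2482194	35.8
chr13	115169878	1814242	17.9
chr14	107349540	1712799	17.6
chr15	102531392	1577346	19
chr16	90354753	1747136	36.6
chr17	81195210	1491841	24
chr18	78077248	1448602	17.2
chr19	59128983	1171356	26.5
chr20	63025520	1206753	27.5
chr21	48129895	787784	13.2
chr22	51304566	745778	14.7
chrX	155270560	2174952	60.6
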