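# Deletions detected by oaCGH in the experimental C. elegans populations after
# 180-212 generations of population expansion (WormBase WS243 coordinates,
# 1-based inclusive).  The trna column counts tRNA/rRNA features for this
# table.  One row (19C V) has a typographically ambiguous feature-count field
# in the source rendering and is stored as NA.
population	chromosome	start	end	span_bp	protein_coding	trna	pirna	ncrna	pseudogene	transposon	copy_number	breakpoint_resolved	coordinate_adjusted
16A	X	817573	830086	12514	1	0	0	0	0	0	0.05	1	0
16D	V	7663133	7687447	24315	7	0	0	0	0	0	0.05	1	0
19A	X	800773	827100	26328	5	0	1	0	0	0	0.47	1	0
19C	V	7642395	7682740	40346	NA	NA	NA	NA	NA	NA	0.23	0	0
19E	X	821499	829454	7956	1	0	0	0	0	0	0.19	0	0
50B	V	7650284	7693435	43152	12	0	0	0	1	0	0.76	0	0
50C	V	7647125	7696096	48972	14	0	0	0	1	0	0.71	0	0
50C	X	1029	273082	272054	35	0	0	14	18	5	0.85	0	0
50D	V	7653667	7680465	26799	6	0	0	0	0	0	0.18	1	0
50D	X	1029	295671	294643	38	0	0	15	20	6	0.81	0	0
50E	V	7652044	7682914	30871	8	0	0	0	0	0	0.47	1	0
66B	V	15258727	15326180	67454	26	0	1	2	5	1	0.62	0	0
66B	X	9983441	9999107	15667	2	0	0	1	0	0	0.04	1	0
66D	V	18665661	18670354	4694	1	0	0	0	0	0	0.54	0	0
66D	V	18701820	18725404	23585	3	0	0	3	5	0	0.39	0	0
66D	X	961361	963014	1654	1	0	0	0	0	0	0.09	0	0
66D	X	7528608	7529729	1122	1	0	0	0	0	0	0.07	0	0
66E	X	7528608	7529729	1122	1	0	0	0	0	0	0.06	0	0
C1	I	15060622	15071438	10817	0	4	0	4	1	0	0.75	0	0
C2	I	15060388	15071427	11040	0	4	0	4	1	0	0.66	0	0
C3	II	14034460	14039471	5012	1	0	0	0	0	0	0.45	0	0
C3	X	7527813	7529236	1424	1	0	0	0	0	0	0.05	1	0
C4	I	15060388	15071427	11040	0	4	0	4	1	0	0.60	0	0
C5	I	15061973	15071438	9466	0	4	0	3	0	0	0.79	0	0
C5	X	823167	827286	4120	1	0	0	0	0	0	0.38	0	0
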