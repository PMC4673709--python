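# Duplications detected by oaCGH in the experimental C. elegans populations after
# 180-212 generations of population expansion (WormBase WS243 coordinates,
# 1-based inclusive).  Feature-count columns whose digit grouping is
# typographically ambiguous in the source rendering are stored as NA rather
# than guessed.  Rows with coordinate_adjusted=1 had a stop coordinate that was
# internally inconsistent with the printed span (rendering corruption); stop is
# stored as start + span - 1.
population	chromosome	start	end	span_bp	protein_coding	trna	pirna	ncrna	pseudogene	transposon	copy_number	breakpoint_resolved	coordinate_adjusted
7B	IV	6837055	6879497	42443	NA	NA	NA	NA	NA	NA	2.19	0	0
7B	V	19505848	20101145	595298	NA	NA	NA	NA	NA	NA	1.62	0	0
7D	IV	505050	701113	196064	NA	NA	NA	NA	NA	NA	1.72	0	0
16B	V	19295123	19839705	544583	NA	NA	NA	NA	NA	NA	1.19	1	0
16C	IV	9054304	9457751	403448	NA	NA	NA	NA	NA	NA	1.23	0	0
16C	V	800408	1103333	302926	NA	NA	NA	NA	NA	NA	1.59	0	0
16D	II	6248049	6406772	158724	NA	NA	NA	NA	NA	NA	1.53	0	0
16D	V	19746828	19885746	138919	NA	NA	NA	NA	NA	NA	1.46	0	0
16E	V	19295580	19840162	544583	NA	NA	NA	NA	NA	NA	2.08	1	0
19C	V	7637941	7641911	3971	3	0	1	0	0	0	1.50	0	0
19C	II	14037517	14039164	1648	1	0	0	0	0	0	1.74	0	0
19E	X	813802	821373	7572	2	0	0	0	0	0	1.68	0	0
19E	X	829580	835391	5812	2	0	0	0	0	0	1.56	0	1
50A	V	19780484	19972052	191569	NA	NA	NA	NA	NA	NA	1.50	1	0
50A	X	8624771	9024484	399714	NA	NA	NA	NA	NA	NA	1.34	0	0
50B	V	19781064	19972507	191444	NA	NA	NA	NA	NA	NA	1.66	0	0
50C	V	19659829	19976508	316680	NA	NA	NA	NA	NA	NA	1.39	0	1
50D	IV	560240	1024886	464647	NA	NA	NA	NA	NA	NA	1.19	0	0
50D	V	18703541	18723878	20338	4	0	0	2	5	0	1.39	0	0
50D	V	19780935	19966260	185326	NA	NA	NA	NA	NA	NA	1.78	0	0
50E	II	6312598	6444674	132077	NA	NA	NA	NA	NA	NA	1.34	0	0
50E	V	19780952	19966162	185211	NA	NA	NA	NA	NA	NA	1.69	0	0
66C	V	19393526	20054330	660805	NA	NA	NA	NA	NA	NA	1.51	0	0
66E	V	19295300	19839882	544583	NA	NA	NA	NA	NA	NA	1.33	1	0
C2	V	19295101	19839683	544583	NA	NA	NA	NA	NA	NA	1.64	1	0
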