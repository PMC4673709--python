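# Single-worm PCR assays of CNV frequency at ~80, ~140 and ~200 generations of
# population expansion, with the printed Hardy-Weinberg frequency and the
# average copy-number per haploid genome from three methods (single-worm PCR,
# qPCR, oaCGH).  chromosome_class records whether the locus is autosomal
# (Hardy-Weinberg estimator) or X-linked (direct hemizygous-male estimator).
# flag values:
#   ok                       row is internally consistent
#   counts_exceed_sample     printed positives exceed printed sample size;
#                            counts unusable
#   printed_freq_mismatch    printed frequency does not equal the estimator
#                            applied to the printed counts (2 dp)
population	generation	cnv_type	chromosome	chromosome_class	n_sampled	n_positive	printed_frequency	printed_copy_number	copy_qpcr	copy_oacgh	flag
16B	80	duplication	V	autosome	19	0	0.00	1.00	NA	NA	ok
16B	140	duplication	V	autosome	47	0	0.00	1.00	0.86	NA	ok
16B	200	duplication	V	autosome	43	28	0.41	1.41	1.02	1.19	ok
16E	80	duplication	V	autosome	30	1	0.02	1.02	1.08	NA	ok
16E	140	duplication	V	autosome	30	25	0.59	1.59	1.58	NA	ok
16E	200	duplication	V	autosome	18	18	1.00	2.00	2.39	2.08	ok
66E	140	duplication	V	autosome	27	10	0.20	1.20	1.23	NA	printed_freq_mismatch
66E	200	duplication	V	autosome	28	22	0.54	1.54	1.67	1.33	ok
16A	140	deletion	X	X	30	30	1.00	0.00	0.00	NA	ok
16A	200	deletion	X	X	27	27	1.00	0.00	0.00	0.05	ok
16D	80	deletion	V	autosome	18	15	0.64	0.36	0.22	NA	printed_freq_mismatch
16D	140	deletion	V	autosome	18	28	1.00	0.00	0.000232	NA	counts_exceed_sample
16D	200	deletion	V	autosome	29	29	1.00	0.00	0.000738	0.05	ok
66B	80	deletion	X	X	32	0	0.00	1.00	0.73	NA	ok
66B	140	deletion	X	X	15	9	0.60	0.40	0.40	NA	ok
66B	200	deletion	X	X	28	28	1.00	0.00	0.0000269	0.04	ok
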