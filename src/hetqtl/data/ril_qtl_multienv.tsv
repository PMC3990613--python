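trait	qtl	environment	marker_lo	marker_hi	cm_lo	cm_hi	peak_cm	chrom	r2_pct	additive_effect	lod_threshold	lod	printed_mean_lod	n_genes
DTH	qdth-1	2009-Beaumont	RM231	RM489	0	13.6	0.2	3	12.7	-4.0	3.6	5.8	7.6	176
DTH	qdth-1	2009-Stuttgart	RM231	RM489	0	13.6	0	3	10.2	-3.0	3.6	11.2	7.6	176
DTH	qdth-1	2010-Stuttgart	RM231	RM489	0	13.6	4	3	11.3	-3.5	3.6	10.5	7.6	176
DTH	qdth-1	2010-Beaumont	RM231	RM489	0	13.6	5	3	9.6	-2.8	3.5	7.5	7.6	176
DTH	qdth-1	2011-Stuttgart	RM231	RM489	0	13.6	1	3	7.1	-2.4	3.8	4.9	7.6	176
DTH	qdth-1	2012-Stuttgart	RM231	RM489	0	13.6	2.1	3	8.13	-2.8	3.5	5.53	7.6	176
DTH	qdth-2	2009-Stuttgart	RM15766	RM15824	107.2	113.5	108.6	3	3.3	-1.7	3.6	3.5	6.1	321
DTH	qdth-2	2010-Beaumont	RM15824	RM6759	113.5	128.8	122.6	3	12.4	-3.1	3.5	8.7	6.1	321
DTH	qdth-5	2010-Stuttgart	Con673	RM527	21	33.5	31.4	6	49.9	11.3	3.6	43.2	25.0	126
DTH	qdth-5	2009-Beaumont	Con673	RM527	21	33.5	30.5	6	21.0	8.6	3.6	8.4	25.0	126
DTH	qdth-5	2010-Beaumont	MRG2431	RM527	30.4	33.5	31.3	6	17.4	5.7	3.5	15.7	25.0	126
DTH	qdth-5	2009-Stuttgart	MRG2431	RM527	30.4	33.5	31.5	6	49.9	9.9	3.6	43.5	25.0	126
DTH	qdth-5	2011-Stuttgart	Con673	MRG2431	21	30.4	29.1	6	40.7	9.9	3.8	23.7	25.0	126
DTH	qdth-5	2012-Stuttgart	Con673	RM527	21	33.5	29	6	25.2	7.5	3.5	15.4	25.0	126
DTH	qdth-6	2010-Beaumont	RM125	RM418	14.1	28.9	23	7	10.4	-2.9	3.4	9.4	9.4	359
DTH	qdth-7	2009-Stuttgart	RM1362	RM248	74.8	78.4	78	7	3.0	1.7	3.6	3.4	5.5	41
DTH	qdth-7	2010-Stuttgart	RM1362	RM248	74.8	78.4	78	7	7.4	2.9	3.6	8.1	5.5	41
DTH	qdth-7	2009-Beaumont	RM1362	RM248	74.8	78.4	78	7	7.5	3.1	3.6	3.6	5.5	41
DTH	qdth-7	2011-Stuttgart	RM118	RM248	63.1	78.4	78	7	8.3	2.7	3.8	6.0	5.5	41
DTH	qdth-7	2012-Stuttgart	RM1362	RM248	74.8	78.4	78	7	8.4	2.9	3.5	6.3	5.5	41
PHT	qpht-1	2009-Beaumont	RM486	RM315	124.7	131.4	130.6	1	22.8	8.8	3.8	7.4	16.9	147
PHT	qpht-1	2009-Stuttgart	RM486	RM315	124.7	131.4	131	1	32.0	12.4	3.5	21.4	16.9	147
PHT	qpht-1	2010-Stuttgart	RM486	RM315	124.7	131.4	130.6	1	29.2	9.7	3.6	22.1	16.9	147
PHT	qpht-1	2010-Beaumont	RM486	RM315	124.7	131.4	130.6	1	21.7	7.2	3.4	17.8	16.9	147
PHT	qpht-1	2011-Stuttgart	RM486	RM315	124.7	131.4	130.6	1	28.6	9.3	3.7	19.1	16.9	147
PHT	qpht-1	2012-Stuttgart	RM486	RM315	124.7	131.4	130.6	1	21.0	8.4	3.4	13.4	16.9	147
PHT	qpht-5	2011-Stuttgart	RM162	RM5371	55	63.8	62	6	7.0	-5.3	3.7	5.0	5.0	81
PHT	qpht-7	2010-Beaumont	RM107	LJSSR1	66.3	77.1	69.4	9	7.7	4.2	3.4	6.1	5.1	137
PHT	qpht-7	2009-Stuttgart	RM107	LJSSR1	66.3	77.1	71.4	9	4.6	4.4	3.5	4.1	5.1	137
PTY	qpty-3	2010-Stuttgart	RM434	LJSSR1	48.3	77.1	70.2	9	48.6	-1.1	3.5	36.6	31.80	477
PTY	qpty-3	2009-Beaumont	RM434	LJSSR1	48.3	77.1	66.3	9	37.9	-1.6	4	13.2	31.80	477
PTY	qpty-3	2010-Beaumont	RM107	LJSSR1	66.3	77.1	69.6	9	58.8	-1.2	3.6	45.6	31.80	477
PTY	qpty-3	2009-Stuttgart	RM107	LJSSR1	66.3	77.1	69.7	9	43.0	-1.3	3.4	32.7	31.80	477
PTY	qpty-3	2011-Stuttgart	RM434	LJSSR1	48.3	77.1	61.6	9	50.9	-1.5	3.7	25.2	31.80	477
PTY	qpty-3	2012-Stuttgart	RM107	LJSSR1	66.3	77.1	70.5	9	66.7	-1.4	3.6	37.56	31.80	477
NOT	qnot-2	2010-Beaumont	RM452	RM475	33.6	60.9	46.6	2	8.3	2.9	3.5	6.4	6.4	410
NOT	qnot-4	2009-Beaumont	RM15824	RM514	113.5	145.5	131	3	13.7	-4.0	3.9	5.0	5.0	583
NOT	qnot-5	2010-Beaumont	RM451	RM124	74.4	104	82.2	4	9.5	-3.0	3.5	6.8	6.1	541
NOT	qnot-5	2011-Stuttgart	RM348	RM124	87.8	104	99.5	4	10.0	-2.2	3.5	5.4	6.1	541
NOT	qnot-6	2010-Beaumont	RM125	RM418	14.1	28.9	18.9	7	7.9	2.8	3.5	5.8	5.1	515
NOT	qnot-6	2011-Stuttgart	RM5711	RM125	0	14.1	10.9	7	8.2	2.0	3.5	4.5	5.1	515
NOT	qnot-7	2010-Beaumont	RM434	LJSSR1	48.3	77.1	70.8	9	9.7	-3.1	3.5	7.3	6.3	477
NOT	qnot-7	2011-Stuttgart	RM434	LJSSR1	48.3	77.1	67.2	9	9.2	-2.2	3.5	5.9	6.3	477
NOT	qnot-7	2012-Stuttgart	RM107	LJSSR1	66.3	77.1	74.3	9	9.4	-2.1	3.6	5.6	6.3	477
PLE	qple-1	2009-Beaumont	RM302	RM315	115.6	131.4	131	1	16.9	1.2	3.6	5.1	5.1	302
PLE	qple-2	2011-Stuttgart	RM450	RM166	97.5	126.4	115.2	2	7.7	-0.7	3.6	5.1	5.1	504
PLE	qple-5	2009-Stuttgart	RM5711	RM2	0	23.9	16.3	7	7.9	-0.8	3.5	5.3	6.7	515
PLE	qple-5	2011-Stuttgart	RM2	RM560	23.9	35.1	28.9	7	10.4	-0.7	3.6	8.1	6.7	515
NOB	qnob-2	2009-Stuttgart	RM452	RM475	33.6	60.9	44.6	2	11.3	-0.5	3.5	6.3	6.3	410
NOB	qnob-4	2009-Beaumont	RM149	RM5493	71.5	88.1	84.5	8	21.0	1.0	4.1	5.5	5.5	116
NOK	qnok-3	2009-Stuttgart	RM341	RM475	52.9	60.9	62.2	2	8.6	-13.3	3.8	6.5	6.5	54
KWP	qkwp-2	2009-Stuttgart	RM486	RM315	124.7	131.4	130.7	1	8.5	0.3	3.6	6.6	6.6	147
KWP	qkwp-3	2009-Stuttgart	RM341	RM5427	52.9	68.3	61.1	2	7.0	-0.3	3.6	5.6	5.6	122
KWP	qkwp-5	2009-Beaumont	RM5711	RM2	0	23.9	17.2	7	16.6	-0.4	3.8	5.5	5.5	515
KWP	qkwp-5	2009-Stuttgart	RM125	RM418	14.1	28.9	20.3	7	9.1	-0.4	3.6	6.0	5.5	515
KWP	qkwp-5	2012-Stuttgart	RM2	RM418	23.9	28.9	26.1	7	7.7	-0.3	3.3	5.0	5.5	515
KWP	qkwp-8	2009-Beaumont	RM254	RM224	66.1	78.1	77.2	11	14.4	-0.4	3.8	5.6	5.6	124
TGW	qtgw-2	2009-Stuttgart	RM413	RM169	13.3	45.4	14.5	5	9.2	1.3	3.7	7.8	6.5	279
TGW	qtgw-2	2009-Beaumont	RM437	RM169	23	45.4	28.6	5	17.7	1.5	3.6	4.8	6.5	279
TGW	qtgw-2	2011-Stuttgart	RM437	RM169	23	45.4	29.6	5	13.5	1.4	3.4	5.6	6.5	279
TGW	qtgw-2	2012-Stuttgart	RM437	RM169	23	45.4	28.6	5	15.3	1.3	3.7	7.8	6.5	279
TGW	qtgw-5	2009-Stuttgart	RM5371	RM340	63.8	82.6	80.7	6	8.0	-1.1	3.7	6.3	6.3	190
TYP	qtyp-4	2009-Beaumont	RM6863	RM310	2.8	16.5	11.6	8	14.1	-10.4	3.5	5.4	5.7	442
TYP	qtyp-4	2011-Stuttgart	RM310	MJIndel1	16.5	31.5	23	8	14.2	-9.5	3.8	6.1	5.7	442
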