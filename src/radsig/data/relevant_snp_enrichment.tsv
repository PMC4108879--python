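chrom	n_snps	variant_freq_pct	expected_by_chance	found	p_value
1	694366	11.11	260	322	0.0017
2	520483	10.07	165	0	<1e-6
3	507286	10.59	175	6	<1e-6
4	476118	10.13	152	0	<1e-6
5	494216	8.99	127	106	ns
6	508735	9.47	144	12	<1e-6
7	405410	9.99	126	74	0.0001
8	444234	9.03	115	281	<1e-6
9	361325	8.98	92	0	<1e-6
10	398909	6.34	49	724	<1e-6
11	258748	12.11	111	19	<1e-6
12	395053	10.34	131	113	ns
13	397581	9.16	106	89	ns
14	345482	12.94	163	0	<1e-6
15	337079	9.37	93	65	0.0157
16	304953	7.54	55	2	<1e-6
17	265557	10.98	98	16	<1e-6
18	289416	8.71	70	0	<1e-6
19	221786	8.72	54	17	6.3e-6
X	222912	4.95	15	0	3.1e-5
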