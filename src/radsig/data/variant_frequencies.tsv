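chrom	n_snps	n_polymorphic	polymorphic_variant_freq_pct	overall_variant_freq_pct
1	694366	341063	22.62	11.11
2	520483	262264	19.99	10.07
3	507286	229264	23.42	10.59
4	476118	219418	21.97	10.13
5	494216	211104	21.05	8.99
6	508735	232322	20.74	9.47
7	405410	207630	19.50	9.99
8	444234	218490	18.36	9.03
9	361325	183990	17.64	8.89
10	398909	124856	20.10	6.34
11	258748	146431	21.39	12.11
12	395053	198106	20.62	10.34
13	397581	181873	20.01	9.16
14	345482	213003	20.98	12.94
15	337079	150984	20.91	9.37
16	304953	114988	19.99	7.54
17	265557	135794	21.48	10.98
18	289416	119201	21.14	8.71
19	221786	94203	20.53	8.72
X	222912	44286	24.91	4.95
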