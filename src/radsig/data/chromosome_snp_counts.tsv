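chrom	n_snps
1	694366
2	520483
3	507286
4	476118
5	494216
6	508735
7	405410
8	444234
9	361325
10	398909
11	258748
12	395053
13	397581
14	345482
15	337079
16	304953
17	265557
18	289416
19	221786
X	222912
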