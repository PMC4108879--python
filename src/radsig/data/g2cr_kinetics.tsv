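strain	n_replicates	k	T	auf
A/J	3	239.0	1.44	330.2
AKR/J	1	190.8	1.60	291.4
Balb/cAn	1	340.1	2.31	696.3
Balb/cByJ	3	287.4	1.85	497.1
C3H/HeHsd	1	188.1	1.81	318.4
CBA/Ca	1	177.5	1.92	315.3
CBA/H	3	139.8	3.10	346.8
C57Bl/6J	2	163.9	2.51	355.0
DBA/2J	1	154.7	2.18	302.9
LP	2	193.5	1.87	332.8
NOD/LtJ	1	220.7	1.47	313.8
NON/LtJ	2	427.5	1.14	508.2
NZB/B1NJ	1	202.4	1.44	282.8
SJL/J	1	178.4	1.90	314.0
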