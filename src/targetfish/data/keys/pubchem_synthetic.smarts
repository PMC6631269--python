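# Synthetic reduced key set for the element/ring/feature-count ("pubchem")
# fingerprint family: a package-authored selection spanning element
# presence/abundance, ring-system features and atom-pair/functional-group
# patterns, NOT the original 881-key definition set.
# Dialect: one key per line, "index<TAB>SMARTS[<TAB>min_count]"; the key is
# set when the molecule has at least min_count (default 1) distinct
# substructure matches of the SMARTS.
0	[#6]
1	[#6]	4
2	[#6]	8
3	[#6]	16
4	[#7]
5	[#7]	2
6	[#7]	4
7	[#8]
8	[#8]	2
9	[#8]	4
10	[#16]
11	[#16]	2
12	[#15]
13	F
14	F	2
15	F	3
16	Cl
17	Cl	2
18	Br
19	I
20	[#5]
21	[#14]
22	[R]
23	[R]	8
24	[R2]
25	[r3]
26	[r4]
27	[r5]
28	[r5]	8
29	[r6]
30	[r6]	10
31	[r7]
32	[r8]
33	[aR]
34	c1ccccc1
35	c1ccccc1	2
36	[cR2]
37	[nR]
38	[nR]	2
39	[oR]
40	[sR]
41	[NR]
42	[OR]
43	[SR]
44	[#6]~[#6]
45	[#6]~[#7]
46	[#6]~[#8]
47	[#6]~[#16]
48	[#7]~[#8]
49	[#6]=[#6]
50	[#6]#[#6]
51	[#6]=[#7]
52	[#6]#[#7]
53	[#6]=[#8]
54	[#7]=[#8]
55	[#6]-[F,Cl,Br,I]
56	[OX2H1]
57	[OX2H1]	2
58	[NX3;H2]
59	[NX3;H1]
60	[SX2H1]
61	[CX4;H3]
62	[CX4;H3]	2
63	[CX4;H3]	3
64	[CX3](=[OX1])[OX2H1]
65	[CX3](=[OX1])[OX2][#6]
66	[CX3](=[OX1])[NX3]
67	[CX3;H1]=[OX1]
68	[#6][CX3](=[OX1])[#6]
69	[OX2]([#6])[#6]
70	[SX4](=[OX1])=[OX1]
71	[SX3]=[OX1]
72	[PX4]=[OX1]
73	[$([NX3+](=[OX1])[OX1-]),$([NX3](=[OX1])=[OX1])]
74	[NX3][NX3]
75	[NX2]=[NX2]
76	[NX3][CX3](=[NX2])[NX3]
77	[CX4]([F])([F])F
78	[c][OX2H1]
79	[c][NX3;H2]
80	[c][Cl]
81	[c][F]
82	[c][CX4;H3]
83	[c][OX2][#6]
84	[c][c]([c])[c]
85	c1ccc2ccccc2c1
86	c1ccncc1
87	c1cncnc1
88	c1cc[nH]c1
89	c1ccoc1
90	c1ccsc1
91	C1CCCCC1
92	C1CCNCC1
93	C1COCCN1
94	[#7;R][#6;R][#6;R][#7;R]
95	[#8;R][#6;R][#6;R][#8;R]
96	[#6]([#6])([#6])([#6])[#6]
97	[CX4;H2][CX4;H2][CX4;H2][CX4;H2]
98	[#7]~[#6]~[#6]~[#8]
99	[#8]~[#6]~[#6]~[#8]
100	[#7]~[#6]~[#7]
101	[#8]~[#6]~[#8]
102	[#16]~[#6]~[#7]
103	[F,Cl,Br,I]	2
104	[NX4+,NX3+]
105	[OX1-]
106	[#6;+0;!$([#6]~[#7]);!$([#6]~[#8])]
107	[CX3]=[CX3][CX3]=[CX3]
108	[cH0]
109	[cH0]	3
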