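# Synthetic reduced key set for the generic-functional-group ("substructure")
# fingerprint family: a package-authored selection of common organic
# functional groups, NOT the original 307-key definition set.
# Dialect: one key per line, "index<TAB>SMARTS"; indices are the bit positions.
0	[CX4;H3]
1	[CX4;H2]([#6])[#6]
2	[CX4;H1]([#6])([#6])[#6]
3	[CX4]([#6])([#6])([#6])[#6]
4	[CX3]=[CX3]
5	[CX2]#[CX2]
6	c
7	c1ccccc1
8	[cR2]
9	[NX3;H2][CX4]
10	[NX3;H1]([CX4])[CX4]
11	[NX3]([CX4])([CX4])[CX4]
12	[NX3;H2][c]
13	[NX4+]
14	[NX3][CX3]=[OX1]
15	[NX3;H1][CX3]=[OX1]
16	[CX3](=[OX1])[OX2H1]
17	[CX3](=[OX1])[OX2][#6]
18	[CX3;H1]=[OX1]
19	[#6][CX3](=[OX1])[#6]
20	[OX2H1][CX4]
21	[OX2H1][c]
22	[OX2]([#6])[#6]
23	[OX2H0][c]
24	[SX2H1]
25	[SX2]([#6])[#6]
26	[SX3]=[OX1]
27	[SX4](=[OX1])=[OX1]
28	[SX4](=[OX1])(=[OX1])[NX3]
29	[SX4](=[OX1])(=[OX1])[OX2H1]
30	[NX3][CX3](=[OX1])[NX3]
31	[NX3][CX3](=[OX1])[OX2]
32	[NX3][CX3](=[NX2])[NX3]
33	[CX3](=[NX2])[NX3]
34	[CX3]=[NX2]
35	[NX3][NX3]
36	[NX2]=[NX2]
37	[NX1]#[CX2]
38	[NX3](=[OX1])=[OX1]
39	[$([NX3+](=[OX1])[O-]),$([NX3](=[OX1])=[OX1])]
40	F
41	Cl
42	Br
43	I
44	[CX4]([F,Cl,Br,I])([F,Cl,Br,I])[F,Cl,Br,I]
45	[PX4]
46	[PX4]=[OX1]
47	n
48	o
49	s
50	[nH]
51	[NX2]=[CX3][NX3]
52	[OX2][CX3]=[OX1]
53	[#6]=[#6][CX3]=[OX1]
54	[CX4][OX2][CX4]
55	[C;R][O;R][C;R]
56	[N;R][C;R](=O)
57	[O;R][C;R](=O)
58	[#16;R]
59	[#7;R][#7;R]
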