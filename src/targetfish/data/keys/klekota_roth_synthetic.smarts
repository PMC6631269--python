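# Synthetic reduced key set for the bioactivity-substructure
# ("klekota_roth") fingerprint family: a package-authored selection of
# ring systems and pharmacophoric substructures recurrent in bioactive
# molecules, NOT the original 4860-key definition set.
# Dialect: one key per line, "index<TAB>SMARTS".
0	c1ccccc1
1	c1ccc2ccccc2c1
2	c1ccncc1
3	c1ccc2ncccc2c1
4	c1ccc2[nH]ccc2c1
5	c1ccc2[nH]cnc2c1
6	c1ccc2ocnc2c1
7	c1ccc2scnc2c1
8	c1cncnc1
9	c1cnccn1
10	c1cnncc1
11	c1cc[nH]c1
12	c1cc[nH]n1
13	c1cnn(c1)[#6]
14	c1ccoc1
15	c1ccsc1
16	c1cocn1
17	c1cscn1
18	c1ncc2[nH]cnc2n1
19	C1CCNCC1
20	C1CCNC1
21	C1CNCCN1
22	C1COCCN1
23	C1CCOC1
24	C1CCOCC1
25	C1CCCCC1
26	C1CCCC1
27	C1CC1
28	O=C1CCCCN1
29	O=C1CCCN1
30	O=C1CCCO1
31	O=C1OCCC1
32	c1ccc(-c2ccccc2)cc1
33	c1ccc(Oc2ccccc2)cc1
34	c1ccc(Cc2ccccc2)cc1
35	c1ccc(Nc2ccccc2)cc1
36	[CX4][NX3;H2]
37	[CX4][NX3;H1][CX4]
38	[CX4][NX3]([CX4])[CX4]
39	[NX3][CX3]=[OX1]
40	[NX3][CX3](=[OX1])[NX3]
41	[NX3][CX3](=[OX1])[OX2]
42	[NX3][SX4](=[OX1])=[OX1]
43	[NX3][CX3](=[NX2])[NX3]
44	[CX3](=[OX1])[OX2H1]
45	[CX3](=[OX1])[OX2][CX4]
46	[c][OX2H1]
47	[c][OX2][CX4;H3]
48	[c]F
49	[c]Cl
50	[c]Br
51	[c][CX4]([F])([F])F
52	[c][CX2]#[NX1]
53	[c]C#N
54	[c][$([NX3+](=[OX1])[OX1-]),$([NX3](=[OX1])=[OX1])]
55	[c][NX3;H2]
56	[c][SX4](=[OX1])(=[OX1])[NX3]
57	[c][CX3](=[OX1])[NX3]
58	[c][CX3]=[OX1]
59	[c][NX3;H1][CX3]=[OX1]
60	[NX3;H0]([CX4])([CX4])[CX4;H2][CX4;H2][OX2,NX3]
61	[OX2H1][CX4][CX4][NX3]
62	c1ccc(-n2cccc2)cc1
63	[c][SX4](=[OX1])(=[OX1])[NX3][CX4]
64	[NX3;R]1[CX4][CX4][NX3;R][CX4][CX4]1
65	[nX2]c[nH]
66	[#7;R2]
67	[#7;R][#6;R](=O)[#7;R]
68	[CX4;H2]([c])[NX3]
69	[CX4;H2]([c])[c]
70	O=C([NX3])c1ccccc1
71	[CX3](=O)[CX4][NX3]
72	[SX2][c]
73	[CX4][SX4](=[OX1])=[OX1]
74	[OX2][CX4;H2][CX4;H2][OX2]
75	[NX2]=[CX3]([NX3])[NX3]
76	[c][CX3]=[CX3][CX3]=[OX1]
77	[c][CX4;H2][NX3][CX3]=[OX1]
78	[F,Cl,Br,I][CX4]
79	[#8;R][#6;R][#8;R]
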