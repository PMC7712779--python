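no	gene	product	cds_len	prot_len	pfam_code	pfam_name	scaffold	equivalent_cds
1	defensin_g1	Tenecin-1	225	74	PF01097	Defensin_2	Unplaced
2	defensin_g2	Tenecin-1	225	74	PF01097	Defensin_2	PYGN01002380	C0J52_24001
3	defensin_g3	Tenecin-1	225	74	PF01097	Defensin_2	PYGN01003429
4	defensin_g4	Tenecin-1	225	74	PF01097	Defensin_2	PYGN01003429	C0J52_27569
5	defensin_g5	Tenecin-1	225	74	PF01097	Defensin_2	PYGN01001185	C0J52_22338
6	defensin_g6	Tenecin-1	225	74	PF01097	Defensin_2	PYGN01002380	C0J52_24004
7	defensin_g7	Tenecin-1	225	74	PF01097	Defensin_2	PYGN01002380
8	defensin_g8	Tenecin-1	225	74	PF01097	Defensin_2	PYGN01001185	C0J52_22336
9	defensin_g9	Phormicin	216	71	PF01097	Defensin_2	PYGN01002380	C0J52_24005
10	defensin_g10	Phormicin	216	71	PF01097	Defensin_2	PYGN01001185
11	defensin_g11	Tenecin-1	246	81	PF01097	Defensin_2	PYGN01002380	C0J52_24006
12	defensin_g12	Tenecin-1	246	81	PF01097	Defensin_2	PYGN01001185	C0J52_22340
13	defensin_g13	Defense_Protein_6	228	75	PF01097	Defensin_2	PYGN01001185	C0J52_22339
14	defensin_g14	Defense_Protein_6	228	75	PF01097	Defensin_2	PYGN01001185
15	defensin_g15	Defensin-like	192	63	PF01097	Defensin_2	PYGN01000358	C0J52_20459
16	defensin_g16	Defensin-like	192	63	PF01097	Defensin_2	PYGN01000358	C0J52_20460
17	termicin_g1	Termicin	195	64	PF11415	Toxin_37	PYGN01000196	C0J52_00758
18	termicin_g2	Termicin	195	64	PF11415	Toxin_37	PYGN01002934	C0J52_26761
19	termicin_g3	Termicin	195	64	PF11415	Toxin_37	PYGN01002934	C0J52_26762
20	drosomycin_g1	Drosomycin	201	66	PF00304	Gamma-thionin	Unplaced
21	drosomycin_g2	Drosomycin	201	66	PF00304	Gamma-thionin	PYGN01000062	C0J52_03170
22	drosomycin_g3	Drosomycin	201	66	PF00304	Gamma-thionin	PYGN01000062	C0J52_03171
23	drosomycin_g4	Drosomycin	201	66	PF00304	Gamma-thionin	Unplaced
24	drosomycin_g5	Drosomycin	201	66	PF00304	Gamma-thionin	PYGN01001559	C0J52_12810
25	drosomycin_g6	Drosomycin	216	71	PF00304	Gamma-thionin	PYGN01001559
26	drosomycin_g7	Drosomycin	201	66	PF00304	Gamma-thionin	PYGN01001559	C0J52_12811
27	drosomycin_g8	Drosomycin	201	66	PF00304	Gamma-thionin	PYGN01001559	C0J52_12812
28	drosomycin_g9	Drosomycin	201	66	PF00304	Gamma-thionin	PYGN01001559	C0J52_12813
29	drosomycin_g10	Drosomycin	201	66	PF00304	Gamma-thionin	PYGN01002215	C0J52_23105
30	drosomycin_g11	Drosomycin	201	66	PF00304	Gamma-thionin	PYGN01002215	C0J52_23106
31	drosomycin_g12	Drosomycin	201	66	PF00304	Gamma-thionin	PYGN01002215	C0J52_23107
32	drosomycin_g13	Drosomycin	201	66	PF00304	Gamma-thionin	PYGN01002215	C0J52_23108
33	attacin-like_g1	Attacin-like	357	118	PF03769	Attacin_C	PYGN01001824	C0J52_26498
34	attacin-like_g2	Attacin-like	360	119	PF03769	Attacin_C	PYGN01001824	C0J52_26498
35	attacin-like_g3	Attacin-like	357	118	PF03769	Attacin_C	Unplaced
36	blattellicin_g1	Blattellicin	762	253	PF03769	Attacin_C	PYGN01001824	C0J52_26498
37	blattellicin_g2	Blattellicin	729	242	PF03769	Attacin_C	PYGN01001824	C0J52_26498
38	blattellicin_g3	Blattellicin	804	267	PF03769	Attacin_C	Unplaced
39	blattellicin_g4	Blattellicin	738	245	PF03769	Attacin_C	PYGN01001824	C0J52_26498
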