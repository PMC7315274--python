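scale_id	name	citation	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
C1	Kyte-Doolittle hydrophobicity	Kyte & Doolittle, J Mol Biol 157:105 (1982)	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
C2	Molecular weight	standard residue molecular weights (Da)	89.0	121.0	133.0	147.0	165.0	75.0	155.0	131.0	146.0	131.0	149.0	132.0	115.0	146.0	174.0	105.0	119.0	117.0	204.0	181.0
C3	Bulkiness	Zimmerman, Eliezer & Simha, J Theor Biol 21:170 (1968)	11.5	13.46	11.68	13.57	19.8	3.4	13.69	21.4	15.71	21.4	16.25	12.82	17.43	14.45	14.28	9.47	15.77	21.57	21.67	18.03
C4	Polarity	Grantham, Science 185:862 (1974)	8.1	5.5	13.0	12.3	5.2	9.0	10.4	5.2	11.3	4.9	5.7	11.6	8.0	10.5	10.5	9.2	8.6	5.9	5.4	6.2
C5	Recognition factors	Fraga, Can J Chem 60:2606 (1982)	78	89	81	78	81	84	84	88	87	85	80	94	91	87	95	107	93	89	104	84
C6	Hydrophobicity (Fauchere-Pliska)	Fauchere & Pliska, Eur J Med Chem 18:369 (1983)	0.31	1.54	-0.77	-0.64	1.79	0.0	0.13	1.8	-0.99	1.7	1.23	-0.6	0.72	-0.22	-1.01	-0.04	0.26	1.22	2.25	0.96
C7	HPLC retention coefficient (TFA)	Browne, Bennett & Solomon, Anal Biochem 124:201 (1982)	7.3	-9.2	-2.9	-7.1	19.2	-1.2	-2.1	6.6	-3.7	20.0	5.6	-5.7	5.1	-0.3	-3.6	-4.1	0.8	3.5	16.3	5.9
C8	Ratio hetero end/side	Grantham, Science 185:862 (1974)	0.0	2.75	1.38	0.92	0.0	0.74	0.58	0.0	0.33	0.0	0.0	1.33	0.39	0.89	0.65	1.42	0.71	0.0	0.13	0.2
C9	Average flexibility	Bhaskaran & Ponnuswamy, Int J Pept Protein Res 32:241 (1988)	0.36	0.35	0.51	0.5	0.31	0.54	0.32	0.46	0.47	0.37	0.3	0.46	0.51	0.49	0.53	0.51	0.44	0.39	0.31	0.42
C10	Beta-sheet propensity	Deleage & Roux, Protein Eng 1:289 (1987)	0.709	1.191	0.541	0.567	1.393	0.657	0.863	1.799	0.721	1.261	1.21	0.604	0.354	0.84	0.92	0.928	1.221	1.965	1.306	1.266
C11	Alpha-helix propensity	Deleage & Roux, Protein Eng 1:289 (1987)	1.489	0.966	0.924	1.504	1.195	0.51	1.003	1.003	1.172	1.236	1.363	0.772	0.492	1.164	1.224	0.739	0.785	0.99	1.09	0.787
C12	Beta-turn propensity	Deleage & Roux, Protein Eng 1:289 (1987)	0.788	0.965	1.197	1.149	0.624	1.86	0.97	0.24	1.302	0.67	0.436	1.572	1.415	0.997	0.912	1.316	0.739	0.387	0.546	0.795
C13	Relative mutability	Dayhoff, Schwartz & Orcutt, Atlas Protein Seq Struct 5(3):345 (1978)	100	20	106	102	41	49	66	96	56	40	94	134	56	93	65	120	97	74	18	41
C14	Number of codons	standard genetic code	4	2	2	2	2	4	2	3	2	6	1	2	4	2	6	6	4	4	1	2
C15	Refractivity	Jones, J Theor Biol 50:167 (1975)	4.34	35.77	12.0	17.26	29.4	0.0	21.81	19.06	21.29	18.78	21.64	13.28	10.93	17.56	26.66	6.35	11.01	13.92	42.53	31.53
C16	Transmembrane tendency	Zhao & London, Protein Sci 15:1987 (2006)	0.38	-0.3	-3.27	-2.9	1.98	-0.19	-1.44	1.97	-3.46	1.82	1.4	-1.62	-1.44	-1.84	-2.57	-0.53	-0.32	1.46	1.53	0.49
C17	Accessible residues (%)	Janin, Nature 277:491 (1979)	6.6	0.9	7.7	5.7	2.4	6.7	2.5	2.8	10.3	4.8	1.0	6.7	4.8	5.2	4.5	9.4	7.0	4.5	1.4	5.1
C18	Average area buried	Rose et al., Science 229:834 (1985)	86.6	132.3	97.8	113.9	194.1	62.9	155.8	158.0	115.5	164.1	172.9	103.3	92.9	119.2	162.2	85.6	106.5	141.0	224.6	177.7
C19	Coil propensity	Deleage & Roux, Protein Eng 1:289 (1987)	0.824	0.953	1.197	0.761	0.915	1.251	1.068	0.886	0.897	1.085	0.81	1.167	1.54	0.947	0.893	1.13	1.148	0.772	0.941	1.161
C20	Total beta-strand propensity	Lifson & Sander, Nature 282:109 (1979)	0.92	1.16	0.81	0.94	1.25	0.92	0.93	1.81	0.7	1.3	1.19	0.89	0.4	0.95	0.93	0.95	1.12	2.63	1.54	1.53
C21	Parallel beta-strand propensity	Lifson & Sander, Nature 282:109 (1979)	1.0	0.91	0.5	0.59	1.3	0.79	0.38	2.6	0.59	1.42	1.49	0.54	0.35	0.28	0.68	0.7	0.59	2.63	1.02	1.08
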