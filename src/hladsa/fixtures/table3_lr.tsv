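subject_id	locus	allele1	allele2	provenance
1	DRB1	DRB1*11		typed
2	A	A*11		typed
3	DQB1	DQB1*03:03		imputed
4	B	B*35		typed
5	DQB1	DQB1*03:01		imputed
6	DQB1	DQB1*03:01		imputed
7	B	B*27		typed
8	B	B*51		typed
9	DQB1	DQB1*03:02		imputed
10	DQB1	DQB1*03:01	DQB1*06:03	imputed
11	DQB1	DQB1*03:02		imputed
12	DQB1	DQB1*03:01		imputed
13	DQB1	DQB1*02:01		imputed
14	C	C*05:01		imputed
15	A	A*29		typed
15	DQB1	DQB1*03:01		imputed
16	DQB1	DQB1*03:02		imputed
17	DQB1	DQB1*05:01		imputed
18	DRB1	DRB1*13		typed
19	DQB1	DQB1*06:02		imputed
20	B	B*08		typed
21	A	A*02		typed
22	DRB1	DRB1*15		typed
23	DQB1	DQB1*05:01		imputed
24	B	B*52		typed
24	DQB1	DQB1*05:01		imputed
25	A	A*01		typed
26	C	C*04:01	C*06:02	imputed
27	B	B*44		typed
28	DQB1	DQB1*04:02	DQB1*06:03	imputed
29	DPB1			unavailable
30	DPB1			unavailable
31	DQB1	DQB1*04:02	DQB1*03:02	imputed
32	DQB1	DQB1*02:02	DQB1*03:01	imputed
33	B	B*35	B*51	typed
34	A	A*02		typed
34	DQB1	DQB1*05:01		imputed
34	DPB1			unavailable
35	DRB1	DRB1*11		typed
35	DPB1			unavailable
36	A	A*24	A*29	typed
36	B	B*44		typed
37	DRB1	DRB1*03		typed
37	DQB1	DQB1*02:01	DQB1*03:03	imputed
38	B	B*57		typed
38	DRB1	DRB1*15		typed
38	DQB1	DQB1*03:01		imputed
39	A	A*01		typed
39	B	B*15		typed
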