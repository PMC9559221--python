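subject_id	locus	allele1	allele2	provenance
1	DRB1	DRB1*11:04		typed
2	A	A*11:02		typed
3	DQB1	DQB1*03:03		typed
3	DQA1	DQA1*03:02		typed
4	B	B*35:02		typed
5	DQB1	DQB1*03:01		typed
5	DQA1	DQA1*05:05		typed
6	DQB1	DQB1*03:01		typed
6	DQA1	DQA1*05:05		typed
7	B	B*27:02		typed
8	B	B*51:01		typed
9	DQB1	DQB1*03:02		typed
9	DQA1	DQA1*02:01		typed
10	DQB1	DQB1*03:01	DQB1*06:03	typed
10	DQA1	DQA1*05:01	DQA1*01:03	typed
11	DQB1	DQB1*03:02		typed
11	DQA1	DQA1*02:01		typed
12	DQB1	DQB1*03:01		typed
12	DQA1	DQA1*03:02		typed
13	DQB1	DQB1*02:01		typed
13	DQA1	DQA1*05:01		typed
14	C	C*05:01		typed
15	A	A*29:02		typed
15	DQB1	DQB1*03:01		typed
15	DQA1	DQA1*05:01		typed
16	DQB1	DQB1*03:02		typed
16	DQA1	DQA1*03:01		typed
17	DQB1	DQB1*05:01		typed
17	DQA1	DQA1*01:01		typed
18	DRB1	DRB1*13:01		typed
19	DQB1	DQB1*06:02		typed
19	DQA1	DQA1*01:02		typed
20	B	B*08:01		typed
21	A	A*02:01		typed
22	DRB1	DRB1*15:01		typed
23	DQB1	DQB1*05:01		typed
23	DQA1	DQA1*01:01		typed
24	B	B*52:01		typed
24	DQB1	DQB1*05:01		typed
24	DQA1	DQA1*01:01		typed
25	A	A*01:01		typed
26	C	C*04:01	C*06:02	typed
27	B	B*44:03		typed
28	DQB1	DQB1*03:01		typed
28	DQA1	DQA1*06:01		typed
29	DPB1	DPB1*04:02		typed
30	DPB1	DPB1*04:01		typed
31	DQB1	DQB1*04:02	DQB1*03:01	typed
31	DQA1	DQA1*03:01	DQA1*03:02	typed
32	DQB1	DQB1*02:02	DQB1*03:02	typed
32	DQA1	DQA1*02:01	DQA1*03:01	typed
33	B	B*35:01	B*51:01	typed
34	A	A*02:01	A*02:13	typed
34	DQB1	DQB1*05:01		typed
34	DQA1	DQA1*01:01		typed
34	DPB1	DPB1*02:01	DPB1*04:02	typed
35	DRB1	DRB1*11:02		typed
35	DPB1	DPB1*04:01		typed
36	A	A*24:02	A*29:02	typed
36	B	B*44:03		typed
37	DRB1	DRB1*03:01		typed
37	DQB1	DQB1*02:01	DQB1*03:03	typed
37	DQA1	DQA1*05:01	DQA1*03:02	typed
38	B	B*57:03		typed
38	DRB1	DRB1*15:01		typed
38	DQB1	DQB1*03:01		typed
38	DQA1	DQA1*05:01		typed
39	A	A*01:01		typed
39	B	B*15:17		typed
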