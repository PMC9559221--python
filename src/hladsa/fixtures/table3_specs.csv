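patient_id,row,beta_alleles,alpha_alleles,mfi_min,mfi_max
1,1,DRB1*11:03,,1462,1462
2,1,A*11:01,,9897,9897
3,1,DQB1*03:03,DQA1*04:01,786,786
4,1,B*35:01;B*35:08,,2425,2425
5,1,DQB1*03:01,DQA1*03:01;DQA1*03:02;DQA1*05:01;DQA1*06:01,1291,2322
6,1,DQB1*03:01,DQA1*05:01;DQA1*06:01,14722,18143
7,1,B*27:03;B*27:05,,1150,1200
8,1,B*51:01,,792,792
9,1,DQB1*03:02,DQA1*02:01;DQA1*03:01;DQA1*03:02,14825,15601
10,1,DQB1*03:01,DQA1*03:01;DQA1*03:02;DQA1*05:01;DQA1*06:01,16816,18520
10,2,DQB1*06:03,DQA1*01:03,1964,1964
11,1,DQB1*03:02,DQA1*02:01,1958,1958
12,1,DQB1*03:01,DQA1*03:02;DQA1*05:01;DQA1*06:01,3672,6355
13,1,DQB1*02:01,DQA1*05:01,6603,6603
14,1,C*05:01,,4303,4303
15,1,A*29:01;A*29:02,,2494,3990
15,2,DQB1*03:01,DQA1*03:01;DQA1*03:02;DQA1*05:01;DQA1*06:01,7019,13441
16,1,DQB1*03:02,DQA1*02:01;DQA1*03:01;DQA1*03:02,7005,7752
17,1,DQB1*05:01,DQA1*01:01,5186,5186
18,1,DRB1*13:01,,1966,1966
19,1,DQB1*06:02,DQA1*01:02,18641,18641
20,1,B*08:01,,1871,1871
21,1,A*02:01;A*02:02;A*02:03,,1171,2342
22,1,DRB1*15:01;DRB1*15:02;DRB1*15:03,,1616,6493
23,1,DQB1*05:01,DQA1*01:01;DQA1*01:02,1123,1375
24,1,B*52:01,,1050,1050
24,2,DQB1*05:01,DQA1*01:01;DQA1*01:02,1990,2300
25,1,A*01:01,,7900,7900
26,1,C*04:01,,1182,1182
26,2,C*06:02,,1159,1159
27,1,B*44:03,,2000,2000
28,1,DQB1*03:01,DQA1*03:02;DQA1*05:01;DQA1*06:01,1150,1907
29,1,DPB1*04:02,DPA1*01:03;DPA1*03:01,816,4008
30,1,DPB1*04:01,DPA1*04:01,4347,4347
31,1,DQB1*04:02,DQA1*03:01,2514,2514
31,2,DQB1*03:01,DQA1*03:02,2621,2621
31,3,DQB1*03:02,DQA1*02:01;DQA1*03:01;DQA1*03:02,6809,6809
32,1,DQB1*02:02,DQA1*02:01;DQA1*03:02;DQA1*05:01,12406,13055
32,2,DQB1*03:02,DQA1*02:01;DQA1*03:01;DQA1*03:02,1512,13991
33,1,B*35:08,,1989,1989
33,2,B*51:01,,1401,1401
34,1,A*02:05,,2685,2685
34,2,DQB1*05:01,DQA1*01:01;DQA1*01:02,2694,7438
34,3,DPB1*02:01,DPA1*01:03,8846,8846
34,4,DPB1*04:02,DPA1*01:03;DPA1*03:01,13513,14085
35,1,DRB1*11:01,,4241,4241
35,2,DPB1*04:01,DPA1*01:03;DPA1*02:01,4315,6814
36,1,A*24:02;A*24:03,,4646,10894
36,2,A*29:01,,2464,2464
36,3,B*44:02;B*44:03,,5647,5661
37,1,DRB1*03:01;DRB1*03:02,,1159,1256
37,2,DQB1*02:01,DQA1*02:01,1611,1611
37,3,DQB1*03:03,DQA1*03:02;DQA1*04:01;DQA1*06:01,1278,1689
38,1,B*57:01,,9606,9606
38,2,DRB1*15:01;DRB1*15:02,,2380,3074
38,3,DQB1*03:01,DQA1*03:01;DQA1*03:02;DQA1*05:01;DQA1*06:01,21875,22402
39,1,A*01:01,,2000,2000
39,2,B*15:12,,2000,2000
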