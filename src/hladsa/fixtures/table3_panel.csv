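target
A*01:01
A*02:01
A*02:02
A*02:03
A*02:05
A*11:01
A*11:02
A*24:02
A*24:03
A*29:01
A*29:02
B*08:01
B*15:12
B*15:17
B*27:03
B*27:05
B*35:01
B*35:08
B*44:02
B*44:03
B*51:01
B*52:01
B*57:01
C*04:01
C*05:01
C*06:02
DRB1*03:01
DRB1*03:02
DRB1*11:01
DRB1*11:03
DRB1*11:04
DRB1*13:01
DRB1*15:01
DRB1*15:02
DRB1*15:03
DQB1*02:01/DQA1*02:01
DQB1*02:01/DQA1*05:01
DQB1*02:02/DQA1*02:01
DQB1*02:02/DQA1*03:02
DQB1*02:02/DQA1*05:01
DQB1*03:01/DQA1*03:01
DQB1*03:01/DQA1*03:02
DQB1*03:01/DQA1*05:01
DQB1*03:01/DQA1*06:01
DQB1*03:02/DQA1*02:01
DQB1*03:02/DQA1*03:01
DQB1*03:02/DQA1*03:02
DQB1*03:03/DQA1*03:02
DQB1*03:03/DQA1*04:01
DQB1*03:03/DQA1*06:01
DQB1*04:02/DQA1*03:01
DQB1*05:01/DQA1*01:01
DQB1*05:01/DQA1*01:02
DQB1*06:02/DQA1*01:02
DQB1*06:03/DQA1*01:03
DPB1*02:01/DPA1*01:03
DPB1*04:01/DPA1*01:03
DPB1*04:01/DPA1*02:01
DPB1*04:01/DPA1*04:01
DPB1*04:02/DPA1*01:03
DPB1*04:02/DPA1*03:01
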