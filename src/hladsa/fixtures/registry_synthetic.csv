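allele,eplet,abv
A*11:01,44KM,0
A*11:01,62QE,0
A*11:01,144KR,0
A*11:01,19K,0
A*11:02,44KM,0
A*11:02,62QE,0
A*11:02,144KR,0
DRB1*11:03,13SE,0
DRB1*11:03,57DE,0
DRB1*11:03,70DA,0
DRB1*11:03,71E,0
DRB1*11:04,13SE,0
DRB1*11:04,57DE,0
DRB1*11:04,70DA,0
DRB1*11:04,74EL,0
DRB1*11:01,13SE,0
DRB1*11:01,57DE,0
DRB1*11:01,70DA,0
DRB1*11:01,96EV,0
DRB1*13:01,13SD,0
DRB1*13:01,71AQ,0
DRB1*13:01,96H,0
DQA1*04:01,2CQ,0
DQA1*04:01,129QS,0
DQA1*04:01,40GR,1
DQA1*04:01,69T,0
DQA1*04:01,76L,0
DQA1*03:02,2CQ,0
DQA1*03:02,129QS,0
DQA1*03:02,175E,0
DQA1*02:01,34Q,0
DQA1*02:01,130A,0
DQA1*02:01,47KHL,1
DQA1*05:01,34Q,0
DQA1*05:01,130A,0
A*02:05,62GE,0
A*02:05,107W,0
A*02:05,43R,0
A*02:01,62GE,0
A*02:01,107W,0
A*02:01,142MT,0
B*15:12,45EE,0
B*15:12,63QI,0
B*15:12,156WA,0
B*15:17,45EE,0
B*15:17,63QI,0
B*15:17,163EW,0
B*35:08,65QIA,0
B*35:08,76ESI,0
B*35:08,109F,0
B*35:01,65QIA,0
B*35:01,76ESI,0
B*35:01,109F,0
A*29:01,62LQ,0
A*29:01,151AHE,0
A*29:02,62LQ,0
A*29:02,151AHE,0
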