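case_id,condition,diameter_stenosis_pct
1,ARAS,72
2,ARAS,46
3,ARAS,72
4,ARAS,20
5,ARAS,42
6,FMD,43
7,ARAS,53
8,ARAS,76
9,ARAS,67
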