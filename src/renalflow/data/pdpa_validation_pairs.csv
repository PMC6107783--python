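case_id,mPdPa,vPdPa,diameter_stenosis_pct
2,0.981,0.954,46
5,1.016,0.954,42
6,0.958,0.862,43
7,0.903,0.865,53
8,0.872,0.865,76
10R,0.690,0.862,
10L,0.900,0.853,
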