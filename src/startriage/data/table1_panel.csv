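compound,scaffold,rel_activity_mean,rel_activity_sd,score_wt,score_r88c,score_v400m,score_a433e,kb_um,itc_status,itc_kd_um,itc_kd_sd_um
A19,1,122,20,2,4,4,4,283,insoluble,,
A25,1,117,7,2,2,0,2,182,no_binding,,
A29,1,141,11,1,2,0,0,133,no_binding,,
A34,2,127,4,4,4,0,2,178,insoluble,,
A35,2,104,25,4,4,0,4,332,no_binding,,
A41,1,135,59,4,2,0,4,428,kd,8.2,4.5
A49,others,48,12,0,2,4,1,55,kd,3.4,1.3
A52,others,124,3,0,2,0,2,96,insoluble,,
A55,others,127,7,1,2,0,2,46,insoluble,,
A57,others,132,10,0,4,0,0,224,insoluble,,
A58,others,115,3,0,4,4,0,307,kd,6.9,2.5
A66,others,81,0,0,2,2,1,51,kd,44.9,7.0
A71,2,132,5,0,4,4,2,92,kd,7.7,1.3
B12,others,115,19,0,1,0,0,314,no_binding,,
B14,2,111,4,1,1,2,0,94,insoluble,,
B15,2,112,0,2,1,4,1,85,no_binding,,
B29,1,134,4,2,2,4,2,65,insoluble,,
B30,1,124,8,4,4,0,0,106,insoluble,,
B31,1,147,5,4,1,1,1,58,insoluble,,
B34,2,152,13,0,0,0,0,145,no_binding,,
B37,others,140,13,0,0,0,0,88,insoluble,,
B40,others,119,10,4,0,-4,-4,44,insoluble,,
B47,1,122,10,2,1,4,0,61,no_binding,,
B49,others,2.6,2.3,4,2,1,1,45,insoluble,,
B56,1,113,5,4,4,4,0,103,insoluble,,
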