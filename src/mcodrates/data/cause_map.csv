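group,range_start,range_end
COVID19,U071,U072
ILL_DEFINED,R00,R99
DM,E10,E14
NEOPLASMS,C00,D48
CVD,I00,I99
CD,A00,B99
CD,J00,J22
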