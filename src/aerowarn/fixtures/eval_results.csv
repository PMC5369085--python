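case,U_I,U_II,U_III,U_IV,U_V,U_VI,level
A_1,0.4599,0.2930,0.0030,0.0000,0.0033,0.0000,I
A_2,0.1316,0.5421,0.1623,0.0000,0.0115,0.0000,II
A_3,0.9119,0.1142,0.0018,0.0000,0.0040,0.0000,I
A_4,0.1331,0.6136,0.0736,0.0001,0.0121,0.0000,II
A_5,0.1276,0.0308,0.3346,0.4278,0.0608,0.0000,IV
A_6,0.1272,0.0085,0.1554,0.1877,0.3408,0.0000,V
A_7,0.8518,0.1532,0.0025,0.0000,0.0038,0.0000,I
A_8,0.8138,0.1652,0.0029,0.0000,0.0048,0.0000,I
A_9,0.1284,0.3589,0.2323,0.0000,0.0108,0.0000,II
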