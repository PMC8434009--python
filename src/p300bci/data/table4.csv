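subject,lat_vr,lat_ar,amp_vr,amp_ar
S1,410,420,5.65,6.05
S2,390,410,3.7,2.16
S3,390,380,2.72,4.97
S4,420,410,2.49,2.54
S5,440,430,9.05,5.28
S6,460,440,4.35,7.72
S8,420,410,3.8,4.74
S9,420,420,7.19,5.62
S10,400,400,2.25,2.94
S11,430,430,2.94,3.09
S14,370,340,4.48,9.01
S15,400,400,3.17,3.1
S16,420,430,1.47,2.24
S17,410,400,3.89,2.76
S18,450,430,3.59,2.86
S19,400,410,22.85,37.05
S20,440,440,2.88,3.53
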