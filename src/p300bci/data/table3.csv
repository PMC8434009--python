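subject,acc_vr,acc_ar,sickness_vr,sickness_ar,preference
S1,90.00,60.00,N,N,VR
S2,66.67,80.00,Y,N,AR
S3,95.00,85.00,N,N,VR
S4,80.00,73.33,N,N,AR
S5,80.00,66.67,N,Y,AR
S6,100.00,100.00,N,N,AR
S8,100.00,100.00,N,N,AR
S9,73.33,86.67,N,N,AR
S10,73.33,93.33,N,N,VR
S11,93.33,100.00,N,N,VR
S14,100.00,73.33,N,N,VR
S15,100.00,100.00,N,N,AR
S16,100.00,93.33,Y,Y,VR
S17,100.00,100.00,N,N,AR
S18,100.00,93.33,N,Y,VR
S19,93.33,100.00,N,N,AR
S20,100.00,100.00,N,N,AR
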