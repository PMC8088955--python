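# AJCC Cancer Staging Manual, 8th edition: lung carcinoma stage grouping for M0.
# Any M1 maps to stage IV (M1a/b/c collapsed); stage 0/occult not represented.
# fixture version 1
T,N,stage
T1a,N0,IA1
T1b,N0,IA2
T1c,N0,IA3
T2a,N0,IB
T2b,N0,IIA
T3,N0,IIB
T4,N0,IIIA
T1a,N1,IIB
T1b,N1,IIB
T1c,N1,IIB
T2a,N1,IIB
T2b,N1,IIB
T3,N1,IIIA
T4,N1,IIIA
T1a,N2,IIIA
T1b,N2,IIIA
T1c,N2,IIIA
T2a,N2,IIIA
T2b,N2,IIIA
T3,N2,IIIB
T4,N2,IIIB
T1a,N3,IIIB
T1b,N3,IIIB
T1c,N3,IIIB
T2a,N3,IIIB
T2b,N3,IIIB
T3,N3,IIIC
T4,N3,IIIC
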