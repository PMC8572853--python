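# ligand-receptor pairs: study-highlighted interactions plus synthetic pairs for testing
ligand,receptor
Csf1,Csf1r
Il34,Csf1r
Ccl3,Ccr5
Cxcl1,Cxcr2
Il1b,Il1r2
Igf1,Igf1r
Gene0001,Gene0002
Gene0003,Gene0004
Gene0005,Gene0006
Gene0007,Gene0008
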