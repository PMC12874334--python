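IL1_inflammasome	curated IL-1/inflammasome pathway module	Il1a	Il1b	Il1r1	Il1rap	Il1rn	Myd88	Irak1	Irak2	Irak4	Traf6	Nfkb1	Nfkbia	Map3k7	Mapk14	Casp1	Pycard	Nlrp3
IL17_targets	curated IL-17 downstream target module	Cxcl1	Cxcl2	Cxcl5	Ccl20	Lcn2	S100a8	S100a9	Il6	Mmp3	Mmp9	Csf3	Nos2
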