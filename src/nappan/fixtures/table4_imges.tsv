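strain	element	size_kb	n_cds	families	context
A. ferrooxidans ATCC 23270	ICEAfe1	291.3	364	IHF_A	TraFHG
A. ferrooxidans ATCC 23270	ICEAfe2	166.1	197	IHF_A;HU	Type-I RM system
A. ferrooxidans CCM 4253	ICE iMGE4	136.0	144	HU;IHF_A	Type-I RM system
A. ferrooxidans CCM 4253	ICE iMGE10	81.0	95	IHF_A;IHF_B	Type-I RM system/site-specific integrase
A. ferrooxidans CCM 4253	ICE iMGE13	115.0	125	IHF_A;HU;IHF_A	EAL/bcs operon/relaxase-mobilization nuclease
F. caldus ATCC 51756	ICEAca_TY.2	183.3	183	IHF_A	type-I RM system/site-specific integrase
F. caldus SM-1	ICEAca_SM.2	208.3	202	HU	
A. ferrooxidans ATCC 53993	ICE iMGE6	99.6	102	Alba_2	Type-III RM res subunit/brnTA addiction module/mobM relaxase
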