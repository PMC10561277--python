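strain	plasmid	size_kb	n_cds	n_naps	families
A. ferrivorans PQ33	pAfPQ33_1	10.2	10	1	KfrA
A. ferrivorans CF27	AFERRIp	46.4	50	1	KfrA
F. caldus ATCC 51756	pACA1.1	27.5	33	2	KfrA;IHF_A
F. caldus MTH-04	p1	190.8	229	4	HU;HU;IHF_A;HU
F. caldus MTH-04	p2	32.8	66	2	IHF_A;KfrA
F. caldus SM-1	mega plasmid	251.8	255	2	HU;IHF_A
F. caldus SM-1	pLAtc3	29.7	28	1	IHF_A
F. caldus SM-1	pLAtc2	14.1	14	1	IHF_A
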