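lineage_id	species	n_genomes	total_naps	naps_median	naps_range	EbfC	Fis	H-NS	HU	IHF_A	IHF_B	Lrp	SMC	Alba_2	KfrA	NdpA	MukB
AFE	Acidithiobacillus ferrooxidans	14	195	15	10-17	14 (1)	13 (1)	0 (0)	43 (2-5)	58 (2-6)	22 (1-3)	14 (1)	15 (1-2)	11 (1)	5 (1-2)	0 (0)	0 (0)
AFG	Acidithiobacillus ferruginosus	1	12	12	12	1 (1)	1 (1)	0 (0)	3 (3)	2 (2)	1 (1)	1 (1)	1 (1)	0 (0)	2 (2)	0 (0)	0 (0)
AFD	Acidithiobacillus ferridurans	9	134	15	11-17	9 (1)	9 (1)	1 (1)	43 (3-6)	31 (2-5)	14 (1-2)	9 (1)	9 (1)	2 (1)	7 (1-2)	0 (0)	0 (0)
AFP	Acidithiobacillus ferriphilus	9	86	10	6-12	9 (1)	9 (1)	1 (1)	18 (1-3)	18 (1-3)	11 (1-2)	8 (1)	10 (1-2)	0 (0)	2 (1)	0 (0)	0 (0)
AFV	Acidithiobacillus ferrivorans	7	115	16	13-25	7 (1)	7 (1)	6 (1)	18 (1-4)	35 (3-9)	20 (1-7)	9 (1-2)	7 (1)	1 (1)	5 (1-2)	0 (0)	0 (0)
AFN	Acidithiobacillus ferrianus	1	8	8	8	1 (1)	1 (1)	0 (0)	1 (1)	1 (1)	1 (1)	2 (2)	1 (1)	0 (0)	0 (0)	0 (0)	0 (0)
ATH	Acidithiobacillus thiooxidans	21	352	17	11-23	20 (1)	20 (1)	36 (1-3)	91 (1-7)	77 (2-5)	62 (2-6)	21 (1)	21 (1)	0 (0)	1 (1)	0 (0)	3 (1)
ACO	Acidithiobacillus concretivorus	1	14	14	14	1 (1)	1 (1)	1 (1)	4 (4)	3 (3)	2 (2)	1 (1)	1 (1)	0 (0)	0 (0)	0 (0)	0 (0)
ASU	Acidithiobacillus sulfurivorans	1	17	17	17	1 (1)	1 (1)	0 (0)	5 (5)	2 (2)	5 (5)	1 (1)	1 (1)	0 (0)	0 (0)	1 (1)	0 (0)
AMA	Acidithiobacillus marinus	1	9	9	9	1 (1)	1 (1)	0 (0)	2 (2)	1 (1)	1 (1)	1 (1)	1 (1)	1 (1)	0 (0)	0 (0)	0 (0)
AMO	Acidithiobacillus monserratensis	1	10	10	10	1 (1)	1 (1)	0 (0)	1 (1)	1 (1)	3 (3)	1 (1)	1 (1)	0 (0)	1 (1)	0 (0)	0 (0)
FCA	Fervidacidithiobacillus caldus	18	189	10	7-14	18 (1)	18 (1)	0 (0)	42 (1-5)	55 (1-5)	21 (1-2)	0 (0)	18 (1-2)	0 (0)	17 (1-2)	0 (0)	0 (0)
ICO	Igneacidithiobacillus copahuensis	6	38	6	6-7	6 (1)	6 (1)	0 (0)	6 (1)	6 (1)	6 (1)	0 (0)	6 (1)	0 (0)	2 (1)	0 (0)	0 (0)
IYE	Igneacidithiobacillus yellowstonensis	1	5	5	5	1 (1)	1 (1)	0 (0)	1 (1)	1 (1)	0 (0)	0 (0)	1 (1)	0 (0)	0 (0)	0 (0)	0 (0)
AMS	Ambacidithiobacillus sulfuriphilus	1	7	7	7	1 (1)	1 (1)	0 (0)	1 (1)	1 (1)	1 (1)	1 (1)	1 (1)	0 (0)	0 (0)	0 (0)	0 (0)
TTP	Thermithiobacillus tepidarius	1	6	6	6	1 (1)	1 (1)	0 (0)	1 (1)	1 (1)	1 (1)	0 (0)	1 (1)	0 (0)	0 (0)	0 (0)	0 (0)
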