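>orit_region_synthetic 169 bp synthetic transfer-origin-like sequence; two planted inverted repeats (stems 8 and 10 nt, loops 4 nt)
GCCAACACCACTAACTGAGCGGTTCGGTGGGGGGTATGCGGACGTTCAAATATGAACGTC
AGCGAAGTCTACCCGGAACATGAACCACGTCGACTCGATACAGGACTAGGTACGAATAAT
CGTACCTAGGCTAATGCGCATCCTGGCTTAGCGGATGTGCAATACGCCG
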