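>HVS1_synthetic_reference window=16051-16384 ; synthetic stand-in for the rCRS HVS-I window (seeded draw; transversion positions pinned to rCRS alleles)
ATACACACCCTAGCACCAGCTGCGGACACACACCCTACTAACATTACTAACAGCTATCAATATCAGCTAA
CCAACACGCCTTGTTAATTTCACACCTAGTACCTCACTATCAGCGCCACTATTCAATATCCAAAAGACTA
CTAAAAACACCACCGCCTCCTAAATCCCATAATTACACCCACTATCAGTCGCAACTTCGTTTTTTCCATT
TCTACGACATCCAAACCCGCATAAAAACTTCTTACAAACTCCGTACTTAGCAAACCTCCTAAAACTGTCC
CAACTAACTTTCGGAAAACCCACGGGAAGACACGCTCTATAAGTGACTCATATT
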