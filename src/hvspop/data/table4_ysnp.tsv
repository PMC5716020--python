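# Y-SNP genotypes of the six Mogou males (raw alleles as printed).
# M175 is a 5-bp deletion: "-5bp" = derived (deleted), "ref" = ancestral.
specimen	M216	M89	M9	M214	M231	M175	M122	M324	P201
MG3	C	T	G	C	G	-5bp	C	G	C
MG9	C	T	G	C	G	-5bp	C	G	C
MG18	C	T	G	C	G	-5bp	C	G	C
MG44	C	T	G	C	G	-5bp	C	G	C
MG48	C	T	G	C	G	-5bp	C	G	C
MG53	C	T	G	C	G	-5bp	C	G	C
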