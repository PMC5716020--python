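# Y-chromosome SNP panel (ISOGG-style rule tree restricted to the typed
# markers). Columns: node<TAB>parent<TAB>marker<TAB>ancestral<TAB>derived
# M175 is a 5-bp deletion; its derived token is "-5bp", ancestral "ref".
# O3a2c/O3a2c1a sit below the typed panel (capture-only markers); their
# alleles are not printed, so genotypes for them use the state tokens
# "anc"/"der" accepted by the caller for any marker.
C	root	M216	C	T
F	root	M89	C	T
K	F	M9	C	G
NO	K	M214	T	C
N	NO	M231	G	A
O	NO	M175	ref	-5bp
O3	O	M122	T	C
O3a	O3	M324	C	G
O3a2	O3a	P201	T	C
O3a2c	O3a2	P164	?	?
O3a2c1a	O3a2c	M117	?	?
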