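# East-Asian mtDNA haplogroup rule tree: the diagnostics typed in the Mogou
# panel (coding-region positions, optional allele suffix; HVS-I positions;
# special markers). Columns: label<TAB>parent<TAB>coding<TAB>hvs1<TAB>special<TAB>flags
# flags: star      - emit "<label>*" when supported with no supported child
#        motif_led - node supported by exact HVS-I transition-motif match,
#                    ancestor evidence waived (low-confidence assignment)
# A coding entry "!P" marks a negative diagnostic (absence of P supports
# the node); used for the M/N basal dichotomy typed at nt10400.
M	root	10400
N	root	!10400			star
D	M	5178			star
D4	D	3010
D5	D	10397
C	M	14318
G	M	4833
Z	M	15784	16185,16223,16260,16298
M7	M	6455
M8	M	15487T
M10	M	10646
M13	M	6023
M25	M		16223,16304		motif_led
A	N	663
B	N			9bp_del
F	N	3970
N9a	N	5417
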