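# mtDNA haplotypes of the 55 Mogou samples: HVS-I motifs (16000+X shorthand),
# diagnostic coding-region SNPs, printed haplotype IDs and haplogroup labels.
# Continuation rows of the printed table (same motif, distinct haplotype ID)
# carry a haplotype_tag marking the untyped distinguishing site.
# Grave IDs are synthetic: carriers of one haplotype share one grave.
haplotype_id	specimens	haplogroup	coding	hvs1	haplotype_tag
ht1	MG28	A	10400,663	086-223-290-319-362
ht2	MG20	A	10400,663	093-129-223-284-290-319-362
ht3	MG23	A	10400,663	051-129-182C-183C-189-290-319-362
ht4	MG24	A	10400,663	223-290-311-319-362
ht5	MG8	B	9bp_del	111-140-183C-189-234-243
ht6	MG57	B	9bp_del	111-140-183C-189-234-243	b
ht7	MG21	C	10400,14318	223-298-327
ht8	MG37	C	10400,14318	223-298-327	b
ht9	MG36	C	10400,14318	093-129-223-298-327
ht10	MG41	C	10400,14318	093-129-188-223-298-327
ht11	MG50,MG51,MG54	C	10400,14318	129-192-223-298-327
ht12	MG38	D*	10400,5178	129-223-362
ht13	MG33	D*	10400,5178	151-223-290-362
ht14	MG11	D4	10400,5178,3010	223-362
ht15	MG22	D4	10400,5178,3010	223-362	b
ht16	MG47,MG52,MG53	D4	10400,5178,3010	223-362	c
ht17	MG3,MG5,MG6	D4	10400,5178,3010	223-274-362
ht18	MG45	D4	10400,5178,3010	223-274-362	b
ht19	MG48	D4	10400,5178,3010	129-223-274-362
ht20	MG4	D4	10400,5178,3010	223-311-362
ht21	MG40	D4	10400,5178,3010	223-343-362
ht22	MG19	D4	10400,5178,3010	223-292-311-328-362
ht23	MG10	D5	10400,5178,10397	126-182C-183C-189-223-362
ht24	MG55	D5	10400,5178,10397	129-164-172-182C-183C-189-223-266-362
ht25	MG58	D5	10400,5178,10397	129-164-172-182C-183C-189-223-266-362	b
ht26	MG18	D5	10400,5178,10397	092-164-172-182C-183C-189-223-266-362
ht27	MG32	D5	10400,5178,10397	092-164-172-182C-183C-189-223-266-362	b
ht28	MG35	F	3970	189-304
ht29	MG42	F	3970	189-304	b
ht30	MG44	F	3970	183C-189-304
ht31	MG31	F	3970	183C-189-232A-249-304
ht32	MG59	G	10400,4833	129-223-261-278-311-362
ht33	MG43	G	10400,4833	086-153-223-278-362
ht34	MG25	M7	10400,6455	223-295-362
ht35	MG27	M7	10400,6455	223-294-295-362
ht36	MG14	M8	10400,15487T	184-223-298-319
ht37	MG9	M10	10400,10646	223-311
ht38	MG29,MG30	M10	10400,10646	223-311	b
ht39	MG49	M10	10400,10646	093-129-193-223-311-357
ht40	MG39	M13	10400,6023	145-188-189-192-223-311-381
ht41	MG60	M25		223-304
ht42	MG2	N*	10398	223-243-256
ht43	MG7	N9a	5417	114-223-261
ht44	MG13	N9a	5417	223-257A
ht45	MG15,MG16,MG17	Z	10400,15784	185-223-260-298
ht46	MG12	Z	10400,15784	185-223-259-260-298
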