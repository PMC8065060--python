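# HLA-DQ mature-chain residues at the nine-residue motif panel plus a few extra
# polymorphic positions. Panel columns (alpha: a1,44,157,196; beta: 9,30,57,70,135)
# are curated from published motif<->allele correspondences; the remaining columns
# (alpha: 22,52,75; beta: 13,26,45,66) are synthetic filler used only to exercise
# polymorphic-position scans and clustering, and do not reproduce IMGT sequences.
allele	chain	a1	22	44	52	75	157	196	9	13	26	30	45	57	66	70	135
DQA1*01:01	alpha	D	Y	R	R	I	A	A
DQA1*01:02	alpha	D	Y	R	R	M	A	A
DQA1*01:03	alpha	D	Y	R	R	V	A	A
DQA1*02:01	alpha	D	F	K	R	I	A	A
DQA1*03:01	alpha	D	Y	Q	H	I	A	A
DQA1*03:02	alpha	D	Y	Q	H	I	D	A
DQA1*03:03	alpha	D	F	Q	H	I	D	A
DQA1*04:01	alpha	G	F	R	H	L	A	T
DQA1*05:01	alpha	D	Y	C	R	L	A	A
DQA1*05:05	alpha	D	Y	C	H	L	A	A
DQA1*05:06	alpha	D	Y	C	R	L	S	A
DQB1*02:01	beta								Y	G	L	S	G	A	E	R	D
DQB1*02:02	beta								Y	G	L	S	G	A	E	R	G
DQB1*03:01	beta								Y	A	Y	Y	E	D	E	R	D
DQB1*03:02	beta								Y	A	Y	Y	G	A	E	R	D
DQB1*03:03	beta								Y	A	L	Y	E	D	E	R	D
DQB1*04:02	beta								Y	G	Y	H	E	D	D	G	D
DQB1*05:01	beta								L	A	G	Y	G	D	E	R	D
DQB1*06:02	beta								F	A	G	Y	E	D	D	G	D
DQB1*06:03	beta								Y	A	G	H	E	D	D	G	D
DQB1*06:04	beta								Y	A	G	H	E	V	D	R	D
DQB1*06:09	beta								Y	A	G	H	G	V	D	G	D
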