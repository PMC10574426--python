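receptor	structure	chain	ligand	affinity
MAPK14	5WJJ	A	Luteolin	-8.194
MAPK1	4QTA	A	Involucratin	-9.624
RELA	6NV2	P	Involucratin	-8.904
TNF	7JRA	A/B/C	Xuelianlactone	-10.01
MAPK8	4QTD	A	Involucratin	-9.794
IL6	7NXZ	A	Quercetin	-7.562
IL1B	5R8Q	A	Flazin	-7.475
CHUK	3BRT	A/C	Flazin	-7.266
IKBKB	3BRT	A/C	Quercetin	-7.174
NFKBIA	1IKN	D	Luteolin	-8.604
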