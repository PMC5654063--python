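# Transcription of a published survey of conserved site-selective A-to-I
# editing substrates in mammals and the stems flanking their edit sites.
# Columns: editing percentage in adult tissue; whether a conserved and a
# stable stem adjacent to (but separate from) the edited stem was found;
# EIE metrics (nt length over both strands, base pairs, transcript distance
# from the edit site; comma-separated when a substrate has several EIEs);
# the EIE side where legible in the source (ambiguous_side=1 where the
# printed 5'/3' marks are typographically garbled and the side is a
# configurable placeholder, not data).
# ND = not determined in the source.
substrate	edit_site	percent_editing	conserved_adjacent_stem	stable_adjacent_stem	eie_length_nt	eie_bp	eie_distance_nt	eie_side	ambiguous_side
GluA2	Q/R	100	yes	yes	102	43	45	3p	0
Gabra3	I/M	92	yes	yes	149	54	143	3p	0
GluA3	R/G	91	yes	yes	81	32	220	3p	1
FLNB	Q/R	90	no	ND	ND	ND	ND	ND	0
Htr2c	I/V	85	yes	yes	64	27	159	3p	1
GluK2	Q/R	83	yes	yes	129,60	42,25	48,32	5p,3p	0
ADAR2	+24	82	yes	yes	86	37	60	3p	1
Cyfip2	K/E	75	yes	yes	116	47	138	3p	1
GluA2	R/G	72	yes	yes	79	30	230	3p	1
GluK1	Q/R	62	yes	yes	73	27	70	3p	1
BLCAP	Y/C	50	yes	yes	71,59,64	33,26,28	37,90,123	3p,3p,3p	1
IGFBP7	K/E	45	no	ND	ND	ND	ND	ND	0
FLNA	Q/R	43	yes	yes	105	36	38	3p	1
Nova1	S/G	30	no	ND	ND	ND	ND	ND	0
KCNA1	I/V	25	no	ND	ND	ND	ND	ND	0
PLCH2	R/G	20	no	ND	ND	ND	ND	ND	0
TMEM63B	Q/R	20	no	ND	ND	ND	ND	ND	0
CCNI	R/G	15	no	ND	ND	ND	ND	ND	0
Azin1	S/G	10	no	ND	ND	ND	ND	ND	0
Copa	I/V	10	no	ND	ND	ND	ND	ND	0
GPATCH8	K/R	10	no	ND	ND	ND	ND	ND	0
NCSTN	S/G	7	no	ND	ND	ND	ND	ND	0
OSGEP	I/M	7	no	ND	ND	ND	ND	ND	0
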