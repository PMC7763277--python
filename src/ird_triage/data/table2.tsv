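family_id	gene	hgvs_c	hgvs_p	status	acmg_class	segregation	solved	reference
17	MFRP	c.498delC	p.(Asn167Thrfs*25)	Hom	5	Yes(3/2)	Yes	[41]
36	RPGR	c.2655_2656del	p.(Glu886Glyfs*192)	Hem	5	Yes(2/5)	Yes	[42]
37	FAM161A	c.1309A>T	p.(Arg437*)	Hom	5	Yes(1/4)	Yes	[43]
40	RP1L1	c.5821C>T	p.(Gln1941*)	Het	5	Yes(1/6)	Yes	ClinVar (361237)
40	RP1L1	c.3412A>G	p.(Lys1138Glu)	Het	3	Yes(1/6)	Yes	This study
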