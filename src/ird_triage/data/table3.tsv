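family_id	gene	hgvs_c	hgvs_p	status	acmg_class	segregation	solved	reference	gnomad_het	gnomad_hem	gnomad_hom	strategy
38	WDFY3	c.2891G>A	p.(Arg964Lys)	Het	3	Yes(1/3)	No	This study		0	0	CES
38	WDFY3	c.10465C>T	p.(Arg3489Cys)	Het	3	Yes(1/3)	No	This study	2	0	0	CES
35	CITED1	c.182C>T	p.(Ala61Val)	Hem	3	Yes(2/3)	No	This study	9	2	0	WES
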