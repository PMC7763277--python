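family_id	gene	hgvs_c	hgvs_p	status	acmg_class	segregation	solved	reference
2	ABCA4	c.3056C>T	p.(Thr1019Met)	Het	5	Yes(1/2)	Yes	[21]
2	ABCA4	c.3364G>A	p.(Glu1122Lys)	Het	5	Yes(1/2)	Yes	[22]
3	CHM	c.1797C>G	p.(Cys599Trp)	Hem	3	No	Yes	This study
4	ABCA4	c.3287C>T	p.(Ser1096Leu)	Het	4	No	Yes	[23]
4	ABCA4	c.466A>G	p.(Ile156Val)	Het	3	No	Yes	[24]
6	EYS	c.4451G>A	p.(Trp1484*)	Het	5	No	Yes	[25]
6	EYS	c.5928-2A>G	r.spl	Het	5	No	Yes	[26]
10	USH2A	c.2299delG	p.(Glu767Serfs*21)	Het	5	Yes(2/5)	Yes	[27]
10	USH2A	c.13374delA	p.(Glu4458Aspfs*3)	Het	5	Yes(2/5)	Yes	[28]
12	PDE6B	c.2193+1G>A	r.spl	Het	5	Yes(2/2)	Yes	[29]
12	PDE6B	c.1572delC	p.(Tyr525Thrfs*50)	Het	5	Yes(2/2)	Yes	This study
13	USH2A	c.2276G>T	p.(Cys759Phe)	Het	5	No	Yes	[30]
13	USH2A	c.13531G>A	p.(Ala4511Thr)	Het	3	No	Yes	[31]
14	WHRN	c.1417-8G>A	r.(spl?)	Hom	3	Yes(2/4)	No	ClinVar (45653)
15	USH2A	c.12546T>G	p.(Asn4182Lys)	Het	3	No	Yes	This study
15	USH2A	c.13979C>G	p.(Pro4660Arg)	Het	3	No	Yes	GnomAD
19	ABCA4	c.5882G>A	p.(Gly1961Glu)	Het	4	Yes(3/3)	Yes	[32]
19	ABCA4	c.700C>T	p.(Gln234*)	Het	5	Yes(3/3)	Yes	[33]
21	USH2A	c.920_923dup	p.(His308Glnfs*16)	Het	5	Yes(2/6)	Yes	[34]
21	USH2A	c.2276G>T	p.(Cys759Phe)	Het	5	Yes(2/6)	Yes	[30]
23	ABCA4	c.3386G>T	p.(Arg1129Leu)	Het	5	Yes(1/4)	Yes	[35]
23	ABCA4	c.700C>T	p.(Gln234*)	Het	5	Yes(1/4)	Yes	[33]
24	ABCA4	c.3386G>T	p.(Arg1129Leu)	Het	5	No	Yes	[35]
24	ABCA4	c.(2382+1_2383-1)_(2587+1_2588-1)del	p.?(Deletion of exon 16)	Het	4	No	Yes	This study
25	BBS10	c.273C>G	p.(Cys91Trp)	Hom	5	Yes(2/2)	Yes	[36]
26	CHM	c.83C>G	p.(Ser28*)	Hem	5	Yes(1/5)	Yes	[37]
28	PDE6B	c.1107+3A>G	r.(spl?)	Het	4	No	Yes	[38]
28	PDE6B	c.1969A>G	p.(Ile657Val)	Het	3	No	Yes	This study
29	PROM1	c.(1002+1_1003-1)_(1454+1_1455-1)del	p.?(Deletion of exons 9-12)	Hom	4	Yes(3/1)	Yes	This study
30	USH2A	c.2276G>T	p.(Cys759Phe)	Het	5	Yes(1/1)	Yes	[30]
30	USH2A	c.6967C>T	p.(Arg2323*)	Het	5	Yes(1/1)	Yes	[39]
31	PDE6B	c.1923_1969delinsTCTGGG	p.(Asn643Glyfs*29)	Hom	5	Yes(1/5)	Yes	[38]
33	USH2A	c.2276G>T	p.(Cys759Phe)	Het	5	Yes(2/2)	Yes	[30]
33	USH2A	c.14011G>T	p.(Glu4671*)	Het	5	Yes(2/2)	Yes	[16]
34	ABCA4	c.5714+5G>A	r.(spl?)	Het	5	Yes(2/3)	Yes	[40]
34	ABCA4	c.223T>G	p.(Cys75Gly)	Het	4	Yes(2/3)	Yes	[22]
35	PDE6B	c.1345C>T	p.(Gln449*)	Het	5	Yes(2/3)	No	dbSNP rs772166846
35	PDE6B	c.1593A>T	p.(=)	Het	4	Yes(2/3)	No	This study
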