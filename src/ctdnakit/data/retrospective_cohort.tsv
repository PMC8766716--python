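patient_id	sex	age	uicc	pt	pn	m	gene	hgvs_c	hgvs_p	imaging_day	ctdna_day	delta
Pat#1	male	77	IV	4	2	1	KRAS	c.35G>A	p.Gly12Asp	764	647	117
Pat#2	male	66	IV	4	2	1	KRAS	c.35G>A	p.Gly12Asp	962	962	0
Pat#3	female	81	III	3	1	0	KRAS	c.35G>T	p.Gly12Val	903	752	151
Pat#4	female	53	IV	3	0	1	KRAS	c.35G>T	p.Gly12Val	226	226	0
Pat#5	female	62	II	4	0	0	KRAS	c.34G>T	p.Gly12Cys	305	n.d	n.a
Pat#6	female	72	IV	3	1	1	KRAS	c.40G>A	p.Val14Ile	163	109	54
Pat#7	male	74	III	3	1	0	KRAS	c.175G>A	p.Ala59Thr	268	42	226
Pat#8	male	63	III	3	1	0	KRAS	c.436G>A	p.Ala146Thr	228	116	112
Pat#9	male	70	III	3	2	0	KRAS	c.350A>G	p.Lys117Arg	397	315	82
Pat#10	male	54	IV	3	2	1	NRAS	c.38G>A	p.Gly13Asp	227	192	35
Pat#11	male	50	IV	4	1	1	NRAS	c.182A>G	p.Gln61Arg	463	326	137
Pat#12	male	54	IV	4	2	1	TP53	c.584T>C	p.Ile195Thr	427	318	109
Pat#13	male	77	IV	4	1	1	TP53	c.743G>A	p.Arg248Gln	269	98	171
Pat#14	male	70	IV	3	1	1	TP53	c.742C>T	p.Arg248Trp	381	195	186
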