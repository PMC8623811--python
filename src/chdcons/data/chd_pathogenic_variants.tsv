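family	hgvs_p	phenotype	inheritance	orthologue_variable_published	paralogue_variable_published
CHD1	p.Arg618Gln	Pilarowski-Bjornsson Syndrome	Autosomal Dominant	No	No
CHD3	p.His886Asp	Snijders Blok-Campeau Syndrome, Intellectual disability	Autosomal Dominant	No	No
CHD3	p.Leu915Phe	Snijders Blok-Campeau Syndrome, Intellectual disability	Autosomal Dominant	No	No
CHD3	p.Arg1121Pro	Snijders Blok-Campeau Syndrome, Intellectual disability	Autosomal Dominant	No	Yes
CHD3	p.Trp1158Arg	Snijders Blok-Campeau Syndrome, Intellectual disability	Autosomal Dominant	No	No
CHD3	p.Asn1159Lys	Snijders Blok-Campeau Syndrome, Intellectual disability	Autosomal Dominant	No	No
CHD3	p.Arg1169Trp	Snijders Blok-Campeau Syndrome, Intellectual disability	Autosomal Dominant	No	No
CHD3	p.Arg1172Gln	Snijders Blok-Campeau Syndrome, Intellectual disability	Autosomal Dominant	No	No
CHD4	p.Ser851Tyr	Sifrim-Hitz-Weiss syndrome	Autosomal Dominant	No	Yes
CHD4	p.Arg1068His	Sifrim-Hitz-Weiss syndrome	Autosomal Dominant	No	Yes
CHD4	p.Glu1094Lys	Sifrim-Hitz-Weiss syndrome	Autosomal Dominant	No	Yes
CHD4	p.Arg1127Gln	Sifrim-Hitz-Weiss syndrome	Autosomal Dominant	No	No
CHD4	p.Trp1148Leu	Sifrim-Hitz-Weiss syndrome	Autosomal Dominant	No	No
CHD4	p.Arg1173Leu	Sifrim-Hitz-Weiss syndrome	Autosomal Dominant	No	No
CHD7	p.Ser834Phe	CHARGE association, Idiopathic hypogonadotropic hypogonadism	Autosomal Dominant	No	No
CHD7	p.Ile1028Val	CHARGE association	Autosomal Dominant	No	Yes
CHD7	p.Cys1101Arg	CHARGE association	Autosomal Dominant	No	Yes
CHD7	p.Leu1294Pro	CHARGE association	Autosomal Dominant	No	No
CHD7	p.Leu1302Pro	CHARGE association	Autosomal Dominant	No	Yes
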