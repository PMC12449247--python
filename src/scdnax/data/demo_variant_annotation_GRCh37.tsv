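chrom	pos	ref	alt	gene	protein_change	coding_effect	function_class	clinvar	dbsnp_id	dann
chr20	31022288	C	A	ASXL1	p.Y591*	nonsense	coding	Likely Pathogenic	rs373145711	0.9967
chr4	55599436	T	C	KIT	p.M541L	missense	coding	Benign	rs3822214	0.6955
chr4	106158216	G	A	TET2	p.P363=	synonymous	coding	Benign	rs7679673	0.52
chr13	28610183	A	G	FLT3	p.L561P	missense	coding	Uncertain Significance	rs12872889	0.88
chr17	7577427	G	A	TP53	p.R306W	missense	coding	Pathogenic	rs121912664	0.97
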