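chrom	start	end	gene	exon	transcript_id	build
chr1	114704460	114716930	NRAS	2	NM_002524.5	GRCh38
chr4	54657918	54740715	KIT	10	NM_000222.3	GRCh38
chr4	105145875	105279816	TET2	3	NM_001127208.3	GRCh38
chr13	28003274	28100592	FLT3	14	NM_004119.3	GRCh38
chr17	7668402	7687550	TP53	8	NM_000546.6	GRCh38
chr20	32358062	32439319	ASXL1	12	NM_015338.6	GRCh38
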