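id	chrom	pos	minor	major	maf
rs10486567	7	27976563	A	G	0.2415
rs38523	7	28039797	C	T	0.3683
rs864745	7	28180556	G	A	0.4965
rs1635852	7	28189411	C	T	0.4973
rs849134	7	28196222	G	A	0.4917
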