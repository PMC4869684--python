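id	chrom	pos	minor	major	maf
rs560887	2	169763148	T	C	0.293
rs138726309	2	169763262	T	C	0.0036
rs2232323	2	169764141	C	A	0.0078
rs492594	2	169764176	C	G	0.4553
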