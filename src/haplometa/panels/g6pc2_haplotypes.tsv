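rs560887	rs138726309	rs2232323	rs492594	frequency
C	C	A	C	0.46
T	C	A	G	0.29
C	C	A	G	0.24
T	C	C	G	0.006
C	T	A	C	0.0009
T	C	A	C	0.0009
C	T	A	G	0.0009
C	C	C	G	0.0009
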