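rs10486567	rs38523	rs864745	rs1635852	rs849134	frequency
G	T	A	T	A	0.2327
G	T	G	C	G	0.2295
G	C	G	C	G	0.1608
G	C	A	T	A	0.1295
A	T	A	T	A	0.0866
A	T	G	C	G	0.0793
A	C	A	T	A	0.0434
A	C	G	C	G	0.0259
A	T	G	T	A	0.0029
A	T	A	C	A	0.0029
A	C	A	C	A	0.0023
G	T	A	C	A	0.0019
G	T	G	T	A	0.0017
G	C	G	T	A	0.0005
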