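gene_id	s1	s2	s3
g1	1	1	0
g2	0	0	1
g3	1	1	1
g4	0	0	1
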