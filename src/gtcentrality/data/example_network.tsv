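g1	g2
g1	g3
g1	g4
g2	g5
g3	g6
g3	g7
g4	g8
g4	g9
g4	g10
g11	g12
g12	g13
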