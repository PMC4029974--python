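protein_a	protein_b	score	string
P1	P2	0.9
P1	P3	0.8
P2	P3	0.7
P3	P4	0.6	0.5
P4	P5	0.5
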