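id	heat	cold
P1	2.5	0.5
P2	1.0	1.0
P3	4.0	0.2
P4	0.1	3.5
P5	1.5	1.5
P6	0.0	0.0
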