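accession	organism	description
P1	A	kinase alpha
P2	A	kinase beta
P3	A	Sensor histidine kinase
P4	B	Sensor regulator
P5	B	transporter
P6	B	orphan
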