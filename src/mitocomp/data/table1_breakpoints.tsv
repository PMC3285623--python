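taxon	Ff	Bn	Ws	Fh	La	Tr	Lr	Lia	Pp	Kt
Ff	0	12	12	13	12	12	12	14	12	12
Bn	12	0	12	12	10	9	14	13	9	9
Ws	12	12	0	13	14	14	14	15	14	14
Fh	13	12	13	0	13	13	14	15	13	13
La	12	10	14	13	0	5	14	13	7	4
Tr	12	9	14	13	5	0	15	13	4	2
Lr	12	14	14	14	14	15	0	15	15	15
Lia	14	13	15	15	13	13	15	0	14	13
Pp	12	9	14	13	7	4	15	14	0	3
Kt	12	9	14	13	4	2	15	13	3	0
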