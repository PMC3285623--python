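unit	A	C	G	T	at_percent	at_skew	gc_skew
atp6	0.213	0.123	0.225	0.439	65.2	-0.347	0.293
atp8	0.306	0.099	0.189	0.405	71.1	-0.139	0.313
cox1	0.227	0.135	0.219	0.419	64.6	-0.297	0.237
cox2	0.225	0.124	0.237	0.414	63.9	-0.296	0.313
cox3	0.196	0.110	0.266	0.426	62.2	-0.370	0.415
cob	0.225	0.130	0.214	0.430	65.5	-0.313	0.244
nad1	0.226	0.103	0.217	0.454	68.0	-0.335	0.356
nad2	0.246	0.104	0.217	0.434	68.0	-0.276	0.352
nad3	0.177	0.105	0.234	0.484	66.1	-0.464	0.381
nad4	0.214	0.106	0.219	0.462	67.6	-0.367	0.348
nad4L	0.212	0.072	0.242	0.474	68.6	-0.382	0.541
nad5	0.217	0.116	0.222	0.445	66.2	-0.344	0.314
nad6	0.187	0.085	0.224	0.503	69.0	-0.458	0.450
rrnS	0.336	0.142	0.215	0.306	64.2	0.047	0.204
rrnL	0.357	0.115	0.197	0.331	68.8	0.038	0.263
entire_genome	0.248	0.114	0.222	0.417	66.5	-0.254	0.321
protein_coding	0.219	0.114	0.224	0.442	66.1	-0.337	0.325
codon_pos1	0.270	0.117	0.257	0.358	62.8	-0.140	0.374
codon_pos2	0.169	0.186	0.183	0.462	63.1	-0.464	-0.008
codon_pos3	0.218	0.042	0.233	0.506	72.4	-0.398	0.695
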