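phylum	taxon	length_bp	A	C	G	T	at_percent	at_skew	gc_skew
Cnidaria	Acropora tenuis	18338	0.251	0.137	0.242	0.370	62.0	-0.192	0.277
Cnidaria	Metridium senile	17443	0.269	0.169	0.212	0.349	61.9	-0.129	0.112
Hemichordata	Balanoglossus carnosus	15708	0.251	0.314	0.171	0.264	51.4	-0.026	-0.295
Echinodermata	Arbacia lixula	15719	0.295	0.205	0.170	0.330	62.5	-0.057	-0.091
Echinodermata	Florometra serratissima	16005	0.264	0.116	0.156	0.464	72.8	-0.274	0.149
Chordata	Homo sapiens	16569	0.309	0.313	0.131	0.247	55.6	0.112	-0.410
Chordata	Xenopus laevis	17553	0.331	0.235	0.135	0.300	63.0	0.049	-0.270
Chaetognatha	Paraspadella gotoi	11423	0.394	0.147	0.125	0.334	72.8	0.081	-0.082
Chaetognatha	Spadella cephaloptera	11905	0.364	0.182	0.167	0.286	65.0	0.120	-0.044
Priapulida	Priapulus caudatus	14919	0.303	0.144	0.165	0.388	69.1	-0.123	0.068
Nematoda	Caenorhabditis elegans	13794	0.314	0.089	0.149	0.448	76.2	-0.175	0.253
Nematoda	Trichinella spiralis	16706	0.405	0.230	0.097	0.265	67.0	0.209	-0.405
Onychophora	Epiperipatus biolleyi	14411	0.320	0.086	0.173	0.421	74.1	-0.135	0.334
Arthropoda	Limulus polyphemus	14985	0.375	0.227	0.097	0.301	67.6	0.111	-0.399
Arthropoda	Heptathela hangzhouensis	14215	0.416	0.172	0.106	0.369	78.6	0.059	-0.235
Arthropoda	Antrokoreana gracilipes	14747	0.298	0.199	0.180	0.323	62.1	-0.041	-0.049
Arthropoda	Lithobius forficatus	15695	0.369	0.204	0.117	0.310	67.9	0.087	-0.269
Arthropoda	Triops cancriformis	15101	0.358	0.182	0.131	0.330	68.8	0.041	-0.163
Arthropoda	Penaeus monodon	15984	0.353	0.167	0.127	0.354	70.6	-0.001	-0.136
Arthropoda	Atelura formicaria	15205	0.348	0.246	0.130	0.276	62.4	0.114	-0.308
Arthropoda	Tribolium castaneum	15881	0.398	0.185	0.098	0.319	71.7	0.109	-0.305
Platyhelminthes	Microcotyle sebastis	14407	0.293	0.097	0.197	0.411	70.4	-0.166	0.341
Platyhelminthes	Echinococcus granulosus	13588	0.191	0.080	0.250	0.479	67.1	-0.430	0.515
Platyhelminthes	Schistosoma japonicum	14085	0.249	0.084	0.206	0.461	71.0	-0.299	0.422
Entoprocta	Loxocorone allax	14862	0.412	0.148	0.118	0.322	73.4	0.123	-0.111
Entoprocta	Loxosomella aloxiata	15323	0.392	0.163	0.131	0.314	70.6	0.110	-0.108
Ectoprocta	Flustrellidra hispida	13026	0.271	0.235	0.176	0.318	58.9	-0.079	-0.142
Ectoprocta	Watersipora subtorquata	14144	0.364	0.163	0.131	0.342	70.6	0.030	-0.108
Ectoprocta	Bugula neritina	15433	0.377	0.176	0.124	0.323	70.0	0.078	-0.173
Ectoprocta	Flustra foliacea	16089	0.248	0.114	0.222	0.417	66.5	-0.254	0.321
Phoronida	Phoronis psammophila	14018	0.334	0.168	0.166	0.332	66.6	0.002	-0.005
Brachiopoda	Lingula anatina	28818	0.261	0.161	0.219	0.359	62.0	-0.158	0.153
Brachiopoda	Terebratulina retusa	15451	0.295	0.277	0.151	0.277	57.2	0.033	-0.294
Brachiopoda	Laqueus rubellus	14017	0.208	0.151	0.265	0.375	58.4	-0.286	0.272
Brachiopoda	Terebratalia transversa	14291	0.199	0.134	0.275	0.392	59.1	-0.328	0.344
Nemertea	Cephalothrix simula	16296	0.275	0.102	0.148	0.474	74.9	-0.266	0.182
Nemertea	Lineus viridis	15388	0.213	0.119	0.224	0.445	65.7	-0.352	0.306
Annelida	Sipunculus nudus	15502	0.268	0.297	0.161	0.274	54.2	-0.013	-0.297
Annelida	Clymenella torquata	15538	0.330	0.195	0.133	0.343	67.2	-0.020	-0.188
Annelida	Urechis caupo	15113	0.315	0.235	0.144	0.305	62.0	0.016	-0.240
Annelida	Platynereis dumerilii	15619	0.312	0.204	0.154	0.329	64.1	-0.026	-0.141
Annelida	Lumbricus terrestris	14998	0.298	0.225	0.158	0.318	61.6	-0.031	-0.176
Mollusca	Katharina tunicata	15532	0.314	0.119	0.186	0.380	69.4	-0.095	0.220
Mollusca	Graptacme eborea	14492	0.370	0.132	0.127	0.371	74.1	-0.002	-0.021
Mollusca	Nautilus macromphalus	16258	0.337	0.285	0.119	0.258	59.6	0.133	-0.412
Mollusca	Loligo bleekeri	17211	0.388	0.195	0.092	0.325	71.3	0.089	-0.358
Mollusca	Octopus vulgaris	15744	0.411	0.176	0.076	0.337	74.9	0.099	-0.397
Mollusca	Pupa strigosa	14189	0.274	0.183	0.205	0.337	61.1	-0.103	0.056
Mollusca	Aplysia californica	14117	0.286	0.154	0.182	0.377	66.3	-0.137	0.085
Mollusca	Biomphalaria glabrata	13670	0.331	0.113	0.141	0.416	74.6	-0.114	0.110
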