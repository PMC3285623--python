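{
 "sha256": {
  "table1_breakpoints.tsv": "50516b6c727fab003dcd8cff7b2fe76cd675f0cf5fe2b0c238c033255e692af8",
  "table2_genomes.tsv": "28a00c1fb0f2a59103009b6a8087e930b10ab22a9813f513aa93e04294a7e0e9",
  "table3_flustra_genes.tsv": "adfef7e154c4926e2bbd651ec288b98f822dda76af50e93e5c93a51b9de366a3",
  "gene_synonyms.tsv": "ef79015c630280006eb71975516bf202d4b5fc1af02d6bdc47c461ffc49be454"
 },
 "non_reproducible_cells": [
  [
   "Acropora tenuis",
   "at_percent",
   62.1,
   62.0
  ],
  [
   "Metridium senile",
   "at_percent",
   61.8,
   61.9
  ],
  [
   "Balanoglossus carnosus",
   "at_percent",
   51.5,
   51.4
  ],
  [
   "Arbacia lixula",
   "gc_skew",
   -0.09333,
   -0.091
  ],
  [
   "Florometra serratissima",
   "gc_skew",
   0.14706,
   0.149
  ],
  [
   "Xenopus laevis",
   "at_percent",
   63.1,
   63.0
  ],
  [
   "Paraspadella gotoi",
   "at_skew",
   0.08242,
   0.081
  ],
  [
   "Paraspadella gotoi",
   "gc_skew",
   -0.08088,
   -0.082
  ],
  [
   "Spadella cephaloptera",
   "gc_skew",
   -0.04298,
   -0.044
  ],
  [
   "Trichinella spiralis",
   "gc_skew",
   -0.40673,
   -0.405
  ],
  [
   "Epiperipatus biolleyi",
   "at_skew",
   -0.1363,
   -0.135
  ],
  [
   "Epiperipatus biolleyi",
   "gc_skew",
   0.33591,
   0.334
  ],
  [
   "Limulus polyphemus",
   "at_skew",
   0.10947,
   0.111
  ],
  [
   "Limulus polyphemus",
   "gc_skew",
   -0.40123,
   -0.399
  ],
  [
   "Heptathela hangzhouensis",
   "at_percent",
   78.5,
   78.6
  ],
  [
   "Heptathela hangzhouensis",
   "gc_skew",
   -0.23741,
   -0.235
  ],
  [
   "Antrokoreana gracilipes",
   "gc_skew",
   -0.05013,
   -0.049
  ],
  [
   "Lithobius forficatus",
   "gc_skew",
   -0.27103,
   -0.269
  ],
  [
   "Penaeus monodon",
   "at_percent",
   70.7,
   70.6
  ],
  [
   "Atelura formicaria",
   "at_skew",
   0.11538,
   0.114
  ],
  [
   "Tribolium castaneum",
   "at_skew",
   0.11018,
   0.109
  ],
  [
   "Tribolium castaneum",
   "gc_skew",
   -0.30742,
   -0.305
  ],
  [
   "Microcotyle sebastis",
   "at_skew",
   -0.16761,
   -0.166
  ],
  [
   "Echinococcus granulosus",
   "at_percent",
   67.0,
   67.1
  ],
  [
   "Schistosoma japonicum",
   "gc_skew",
   0.42069,
   0.422
  ],
  [
   "Loxocorone allax",
   "gc_skew",
   -0.11278,
   -0.111
  ],
  [
   "Flustrellidra hispida",
   "gc_skew",
   -0.14355,
   -0.142
  ],
  [
   "Watersipora subtorquata",
   "at_skew",
   0.03116,
   0.03
  ],
  [
   "Phoronis psammophila",
   "at_skew",
   0.003,
   0.002
  ],
  [
   "Terebratulina retusa",
   "at_skew",
   0.03147,
   0.033
  ],
  [
   "Laqueus rubellus",
   "at_percent",
   58.3,
   58.4
  ],
  [
   "Laqueus rubellus",
   "gc_skew",
   0.27404,
   0.272
  ],
  [
   "Terebratalia transversa",
   "at_skew",
   -0.32657,
   -0.328
  ],
  [
   "Cephalothrix simula",
   "gc_skew",
   0.184,
   0.182
  ],
  [
   "Lineus viridis",
   "at_percent",
   65.8,
   65.7
  ],
  [
   "Sipunculus nudus",
   "at_skew",
   -0.01107,
   -0.013
  ],
  [
   "Clymenella torquata",
   "at_percent",
   67.3,
   67.2
  ],
  [
   "Clymenella torquata",
   "gc_skew",
   -0.18902,
   -0.188
  ],
  [
   "Platynereis dumerilii",
   "gc_skew",
   -0.13966,
   -0.141
  ],
  [
   "Lumbricus terrestris",
   "at_skew",
   -0.03247,
   -0.031
  ],
  [
   "Lumbricus terrestris",
   "gc_skew",
   -0.17493,
   -0.176
  ],
  [
   "Graptacme eborea",
   "gc_skew",
   -0.01931,
   -0.021
  ],
  [
   "Nautilus macromphalus",
   "at_percent",
   59.5,
   59.6
  ],
  [
   "Nautilus macromphalus",
   "gc_skew",
   -0.41089,
   -0.412
  ],
  [
   "Octopus vulgaris",
   "at_percent",
   74.8,
   74.9
  ],
  [
   "Aplysia californica",
   "gc_skew",
   0.08333,
   0.085
  ],
  [
   "Biomphalaria glabrata",
   "at_percent",
   74.7,
   74.6
  ]
 ],
 "note": "cells whose printed derived value is not re-derivable at printed precision from the 3-dp proportions; all lie within the propagated rounding interval"
}
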