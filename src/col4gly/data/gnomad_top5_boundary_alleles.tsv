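#X-linked genotype counts for the five most frequent boundary Gly variants
variant	hem	het	hom
Gly953Val	249	442	7
Gly624Asp	4	12	0
Gly626Ser	2	3	1
Gly1074Ser	4	3	0
Gly961Val	2	3	0
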