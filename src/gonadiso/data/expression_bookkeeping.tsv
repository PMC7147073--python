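quantity	component	value
not_expressed	total	19481
ovary_specific	low	14284
ovary_specific	mid	4242
ovary_specific	high	1190
testis_specific	low	2751
testis_specific	mid	229
testis_specific	high	48
deu	up_ovary	18863
deu	up_testis	5238
de_lncrna	up_ovary	235
de_lncrna	up_testis	726
total_unigenes	total	164618
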