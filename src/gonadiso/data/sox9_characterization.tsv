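name	full_length_bp	orf_bp	utr5_bp	utr3_bp	amino_acids	molecular_weight_kda
Asi_Sox9	2145	1467	116	562	488	54.15
Asc_Sox9-1	2873	1332	367	1174	443	48.98
Asc_Sox9-2	3413	1467	347	1599	488	54.19
Asc_Sox9-3	3429	1464	383	1582	487	53.94
Asc_Sox9-4	3491	1290	604	1597	429	48.04
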