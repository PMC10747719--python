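locus	total_na	amplification_rate_pct
JR01	7	100
JR02	9	97
JR03	7	97
JR04	12	100
JR05	9	100
JR06	6	97
JR07	7	94
JR08	5	100
JR09	8	92
JR10	5	99
JR11	5	100
JR12	6	100
JS02	7	99
JS03	6	98
JS04	7	100
JS05	8	96
JS06	4	98
JS07	6	100
JS09	6	100
JS12	8	100
JS13	6	99
JS14	5	98
JS15	6	100
JS19	10	97
JS22	10	100
JS28	5	99
BFU-Jr277	5	96
BFU-Jr38	12	98
CUJRD102	6	96
CUJRD462	6	100
JM5446	8	100
SSR18	9	100
ZMZ7	8	100
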